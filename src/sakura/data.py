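"""Core expression-matrix container.

The central in-memory object is :class:`ExpressionMatrix`, a cells x genes
matrix (dense ndarray or scipy sparse) together with unique gene and cell
identifiers and a ``layer_tag`` recording which processing stage the values
represent (``raw`` UMI counts, ``lognorm`` library-size log-normalized
values, or ``scaled`` per-gene z-scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

LAYER_TAGS = ("raw", "lognorm", "scaled")


class ValidationError(ValueError):
    """Raised when an input matrix or table violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with identifiers.

    Parameters
    ----------
    values
        ``(M, N)`` array-like, dense or scipy sparse. Non-negative for the
        ``raw`` and ``lognorm`` layers.
    gene_ids
        ``N`` unique gene identifiers (columns).
    cell_ids
        ``M`` unique cell identifiers (rows).
    layer_tag
        One of ``{"raw", "lognorm", "scaled"}``.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.ndim != 2:
                raise ValidationError("values must be 2-dimensional")
        m, n = self.values.shape
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene_{i}" for i in range(n)], dtype=object)
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(m)], dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.gene_ids) != n:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != number of columns {n}"
            )
        if len(self.cell_ids) != m:
            raise ValidationError(
                f"cell_ids length {len(self.cell_ids)} != number of rows {m}"
            )
        if len(set(self.gene_ids)) != n:
            raise ValidationError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != m:
            raise ValidationError("cell_ids contain duplicates")
        if self.layer_tag not in LAYER_TAGS:
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag in ("raw", "lognorm"):
            mn = self.values.min() if self.values.size else 0.0
            if mn < 0:
                raise ValidationError(
                    f"negative entries not allowed in layer {self.layer_tag!r}"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        """Return values as a dense float64 ndarray (copying if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return self.values

    def gene_index(self, gene_id: str) -> int:
        """Column index of ``gene_id``; raises ``KeyError`` if absent."""
        idx = self._gene_lookup().get(gene_id)
        if idx is None:
            raise KeyError(f"gene {gene_id!r} not present in matrix")
        return idx

    def gene_column(self, gene_id: str) -> np.ndarray:
        """Dense 1-D expression vector of one gene across all cells."""
        j = self.gene_index(gene_id)
        col = self.values[:, j]
        if sp.issparse(col):
            col = np.asarray(col.todense()).ravel()
        return np.asarray(col, dtype=np.float64).ravel()

    def _gene_lookup(self) -> dict:
        cache = getattr(self, "_lookup_cache", None)
        if cache is None or len(cache) != self.n_genes:
            cache = {g: j for j, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_lookup_cache", cache)
        return cache

    def subset_genes(self, columns: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the given column indices (order kept)."""
        vals = self.values[:, columns]
        return ExpressionMatrix(
            vals, self.gene_ids[columns], self.cell_ids.copy(), self.layer_tag
        )
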