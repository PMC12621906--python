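"""Minimal pre-processing: log-normalization, HVG selection, scaling, PCA.

Mirrors the standard single-cell recipe (library-size log-normalization with
a fixed scale factor, selection of the highest-variance genes, per-gene
z-scaling) plus the 50-dimensional PCA embedding used as the unsupervised
baseline and by the regularization decision procedure.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .data import ExpressionMatrix, ValidationError

DEFAULT_SCALE_FACTOR = 10_000.0


def log_normalize(
    raw: ExpressionMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ExpressionMatrix:
    """Library-size normalize and log-transform raw counts.

    Each cell's counts are divided by the cell's total count, multiplied by
    ``scale_factor`` and mapped through ``log1p``. Cells with zero total
    count pass through as all-zero rows.
    """
    if raw.layer_tag != "raw":
        raise ValidationError(f"expected raw layer, got {raw.layer_tag!r}")
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    X = raw.values
    if sp.issparse(X):
        X = sp.csr_matrix(X, dtype=np.float64, copy=True)
        totals = np.asarray(X.sum(axis=1)).ravel()
        scale = np.divide(
            scale_factor, totals, out=np.zeros_like(totals), where=totals > 0
        )
        X = sp.diags(scale) @ X
        X.data = np.log1p(X.data)
        out = X
    else:
        totals = X.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(totals > 0, X / totals * scale_factor, 0.0)
        out = np.log1p(norm)
    return ExpressionMatrix(out, raw.gene_ids.copy(), raw.cell_ids.copy(), "lognorm")


def gene_variances(X: ExpressionMatrix, ddof: int = 1) -> np.ndarray:
    """Per-gene variance of the stored values (sample variance by default)."""
    V = X.values
    m = V.shape[0]
    if sp.issparse(V):
        mean = np.asarray(V.mean(axis=0)).ravel()
        sq = np.asarray(V.multiply(V).mean(axis=0)).ravel()
        var = sq - mean**2
        if ddof and m > ddof:
            var = var * m / (m - ddof)
        return np.maximum(var, 0.0)
    return V.var(axis=0, ddof=ddof if m > ddof else 0)


def select_hvg(
    X: ExpressionMatrix,
    n_genes: int,
    force_include: list[str] | None = None,
) -> ExpressionMatrix:
    """Keep the ``n_genes`` genes with the highest variance.

    Original gene order is preserved among the selected genes. Ties at the
    variance cutoff are broken by lexicographically smaller ``gene_id``.
    ``force_include`` genes (e.g. genes of interest) are kept regardless of
    their variance rank, displacing the lowest-variance selected genes.
    """
    if X.layer_tag != "lognorm":
        raise ValidationError(f"expected lognorm layer, got {X.layer_tag!r}")
    if n_genes > X.n_genes:
        raise ValidationError(f"n_genes {n_genes} exceeds gene count {X.n_genes}")
    var = gene_variances(X)
    order = sorted(range(X.n_genes), key=lambda j: (-var[j], X.gene_ids[j]))
    chosen = set(order[:n_genes])
    if force_include:
        lookup = {g: j for j, g in enumerate(X.gene_ids)}
        missing = [g for g in force_include if g not in lookup]
        if missing:
            raise ValidationError(f"force_include genes absent from matrix: {missing}")
        forced = {lookup[g] for g in force_include}
        # evict lowest-ranked non-forced genes to make room
        for j in reversed(order[:n_genes]):
            if len(chosen | forced) <= n_genes:
                break
            if j not in forced:
                chosen.discard(j)
        chosen |= forced
    cols = np.array(sorted(chosen), dtype=int)
    return X.subset_genes(cols)


def scale_genes(X: ExpressionMatrix, clip: float | None = None) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to unit sample s.d.

    Constant genes map to all-zero columns. If ``clip`` is given, scaled
    values are truncated to ``[-clip, +clip]``.
    """
    if X.layer_tag != "lognorm":
        raise ValidationError(f"expected lognorm layer, got {X.layer_tag!r}")
    V = X.dense().copy()
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1) if V.shape[0] > 1 else np.zeros(V.shape[1])
    out = np.where(sd > 0, (V - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if clip is not None:
        if clip <= 0:
            raise ValidationError("clip must be positive")
        out = np.clip(out, -clip, clip)
    return ExpressionMatrix(out, X.gene_ids.copy(), X.cell_ids.copy(), "scaled")


def pca_embed(X: ExpressionMatrix, n_dims: int = 50, seed: int = 0) -> np.ndarray:
    """Top-``n_dims`` principal-component scores of the scaled matrix.

    Components are ordered by decreasing explained variance with a fixed
    sign convention (the largest-magnitude gene loading of each component
    is positive) so the embedding is reproducible. Exact SVD is used up to
    50,000 cells, a seeded randomized solver above.
    """
    if X.layer_tag != "scaled":
        raise ValidationError(f"expected scaled layer, got {X.layer_tag!r}")
    V = X.dense()
    m, n = V.shape
    if n_dims > min(m, n):
        raise ValidationError(f"n_dims {n_dims} exceeds min(M, N) = {min(m, n)}")
    Vc = V - V.mean(axis=0)
    if m <= 50_000:
        U, s, Vt = np.linalg.svd(Vc, full_matrices=False)
    else:  # pragma: no cover - large-data path
        from sklearn.utils.extmath import randomized_svd

        U, s, Vt = randomized_svd(Vc, n_components=n_dims, random_state=seed)
    U, s, Vt = U[:, :n_dims], s[:n_dims], Vt[:n_dims]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return U * s * flip
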