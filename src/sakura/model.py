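"""The knowledge-guided autoencoder: architecture, GOI targets, and losses.

The model is an encoder-decoder pair whose 50-dimensional bottleneck forms
the cell embedding, plus a small regression head attached to the bottleneck
that predicts the expression of user-supplied genes of interest (GOI). Three
loss components drive training:

* ``L_rec`` — L1 + squared-L2 reconstruction error between a cell's input
  profile and the decoder output, weighted by ``lambda1``/``lambda2``;
* ``L_reg`` — sliced 2-Wasserstein distance between the embedding and a
  uniform prior (see :mod:`sakura.regularize`), weighted by ``lambda3``;
* ``L_goi`` — L1 + squared-L2 + per-cell cosine error between the true and
  predicted GOI targets, weighted by ``lambda4``/``lambda5``/``lambda6``.

GOI targets generalize beyond single genes: a target may be a sum of gene
columns (e.g. CD8A + CD8B for the two chains of the CD8 receptor) or the
per-cell minimum of z-scored signature averages (used for combining a CDK
inhibitor score with an aging score).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, ValidationError
from .nn import CELU, Identity, Linear, RMSProp, Sequential

COSINE_EPS = 1e-8
CHECKPOINT_SCHEMA = "sakura-ckpt-1"


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_widths`` are the three hidden-layer widths used on both the
    encoder and decoder side (100 per layer for small data sets, 200 for
    large ones); the bottleneck always defaults to 50 nodes. The GOI head is
    a three-layer fully connected network with two 50-node hidden layers and
    one output node per target.
    """

    input_dim: int
    hidden_widths: tuple[int, int, int] = (100, 100, 100)
    bottleneck_dim: int = 50
    goi_head_hidden: tuple[int, int] = (50, 50)
    activation: str = "celu"
    celu_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.bottleneck_dim >= self.input_dim:
            raise ValidationError("bottleneck_dim must be smaller than input_dim")
        widths = (*self.hidden_widths, self.bottleneck_dim, *self.goi_head_hidden)
        if any(w < 1 for w in widths):
            raise ValidationError("all layer widths must be >= 1")
        if self.activation not in ("celu", "identity"):
            raise ValidationError(f"unknown activation {self.activation!r}")


@dataclass
class LossWeights:
    """Weights of the loss components; all must be non-negative."""

    lambda1: float = 1.0   # reconstruction L1
    lambda2: float = 1.0   # reconstruction squared L2
    lambda3: float = 1.0   # sliced-Wasserstein regularization
    lambda4: float = 1.0   # GOI L1
    lambda5: float = 1.0   # GOI squared L2
    lambda6: float = 1.0   # GOI cosine

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5", "lambda6"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class GOITarget:
    """One regression target: a named function of gene columns."""

    name: str
    kind: str  # gene | sum | min_signature_z
    genes: tuple[str, ...] = ()
    signatures: tuple[tuple[str, ...], ...] = ()


@dataclass
class GOISpec:
    """Ordered list of regression targets."""

    targets: list[GOITarget] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise ValidationError("GOI target names must be unique")
        for t in self.targets:
            if t.kind not in ("gene", "sum", "min_signature_z"):
                raise ValidationError(f"unknown GOI target kind {t.kind!r}")

    def __len__(self) -> int:
        return len(self.targets)

    def all_genes(self) -> list[str]:
        """Every gene referenced by any target, in first-seen order."""
        seen: dict[str, None] = {}
        for t in self.targets:
            for g in t.genes:
                seen.setdefault(g)
            for sig in t.signatures:
                for g in sig:
                    seen.setdefault(g)
        return list(seen)

    def validate_against(self, X: ExpressionMatrix) -> None:
        missing = [g for g in self.all_genes() if g not in set(X.gene_ids)]
        if missing:
            raise ValidationError(f"GOI genes absent from matrix: {missing}")

    # -- plain-text format ----------------------------------------------
    # one directive per line:
    #   gene CD8A
    #   sum CD8 = CD8A + CD8B
    #   minz SEN = [Cdkn1a, Cdkn1b] ; [Gene1, Gene2]
    @classmethod
    def parse(cls, text: str) -> "GOISpec":
        targets: list[GOITarget] = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            kind, _, rest = line.partition(" ")
            rest = rest.strip()
            try:
                if kind == "gene":
                    targets.append(GOITarget(rest, "gene", (rest,)))
                elif kind == "sum":
                    name, expr = (s.strip() for s in rest.split("=", 1))
                    genes = tuple(g.strip() for g in expr.split("+"))
                    targets.append(GOITarget(name, "sum", genes))
                elif kind == "minz":
                    name, expr = (s.strip() for s in rest.split("=", 1))
                    sigs = []
                    for block in expr.split(";"):
                        block = block.strip()
                        if not (block.startswith("[") and block.endswith("]")):
                            raise ValueError("signature must be bracketed")
                        sigs.append(tuple(g.strip() for g in block[1:-1].split(",")))
                    targets.append(
                        GOITarget(name, "min_signature_z", signatures=tuple(sigs))
                    )
                else:
                    raise ValueError(f"unknown directive {kind!r}")
            except ValueError as exc:
                raise ValidationError(f"GOI spec line {lineno}: {exc}") from exc
        return cls(targets)

    @classmethod
    def read(cls, path) -> "GOISpec":
        with open(path) as fh:
            return cls.parse(fh.read())

    def to_text(self) -> str:
        lines = []
        for t in self.targets:
            if t.kind == "gene":
                lines.append(f"gene {t.name}")
            elif t.kind == "sum":
                lines.append(f"sum {t.name} = " + " + ".join(t.genes))
            else:
                sigs = " ; ".join("[" + ", ".join(s) + "]" for s in t.signatures)
                lines.append(f"minz {t.name} = {sigs}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GOI target construction
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()  # population s.d. for signature scoring
    if sd == 0:
        raise ValidationError("constant gene in signature (zero variance)")
    return (v - v.mean()) / sd


def build_goi_targets(X_lognorm: ExpressionMatrix, spec: GOISpec) -> np.ndarray:
    """Evaluate every GOI target on the log-normalized matrix.

    Returns an ``(M, T)`` matrix with one column per target in spec order.
    ``gene`` copies the column, ``sum`` adds member columns, and
    ``min_signature_z`` z-scores the per-cell mean of z-scored signature
    gene columns for each signature, then takes the per-cell minimum.
    """
    if X_lognorm.layer_tag != "lognorm":
        raise ValidationError(
            f"GOI targets are computed on lognorm data, got {X_lognorm.layer_tag!r}"
        )
    spec.validate_against(X_lognorm)
    cols = []
    for t in spec.targets:
        if t.kind == "gene":
            cols.append(X_lognorm.gene_column(t.genes[0]))
        elif t.kind == "sum":
            cols.append(
                np.sum([X_lognorm.gene_column(g) for g in t.genes], axis=0)
            )
        else:  # min_signature_z
            scores = []
            for sig in t.signatures:
                try:
                    zs = np.column_stack(
                        [_zscore(X_lognorm.gene_column(g)) for g in sig]
                    )
                except ValidationError as exc:
                    raise ValidationError(
                        f"signature in target {t.name!r}: {exc}"
                    ) from exc
                scores.append(_zscore(zs.mean(axis=1)))
            cols.append(np.min(np.column_stack(scores), axis=1))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class SakuraModel:
    """Encoder / decoder / GOI-head parameter container."""

    def __init__(self, config: ModelConfig, goi_spec: GOISpec, seed: int = 0):
        self.config = config
        self.goi_spec = goi_spec
        rng = np.random.default_rng(seed)
        act = self._make_activation

        h1, h2, h3 = config.hidden_widths
        d = config.bottleneck_dim
        self.encoder = Sequential([
            Linear(config.input_dim, h1, rng), act(),
            Linear(h1, h2, rng), act(),
            Linear(h2, h3, rng), act(),
            Linear(h3, d, rng),
        ])
        self.decoder = Sequential([
            Linear(d, h3, rng), act(),
            Linear(h3, h2, rng), act(),
            Linear(h2, h1, rng), act(),
            Linear(h1, config.input_dim, rng),
        ])
        g1, g2 = config.goi_head_hidden
        self.goi_head = Sequential([
            Linear(d, g1, rng), act(),
            Linear(g1, g2, rng), act(),
            Linear(g2, max(len(goi_spec), 1), rng),
        ])

    def _make_activation(self):
        if self.config.activation == "identity":
            return Identity()
        return CELU(self.config.celu_alpha)

    # -- forward ---------------------------------------------------------
    def forward(
        self, batch: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(embedding, reconstruction, goi_pred)`` for a batch.

        The GOI prediction is a function of the embedding only; decoder
        parameters never influence it.
        """
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 2 or batch.shape[1] != self.config.input_dim:
            raise ValidationError(
                f"batch has {batch.shape[-1] if batch.ndim == 2 else '?'} columns, "
                f"model expects {self.config.input_dim}"
            )
        h = self.encoder.forward(batch)
        x_rec = self.decoder.forward(h)
        y_pred = self.goi_head.forward(h)
        return h, x_rec, y_pred

    def embed(self, X: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """Encoder applied to every row (no caching side effects retained)."""
        X = np.asarray(X, dtype=np.float64)
        out = [self.encoder.forward(X[i:i + batch_size])
               for i in range(0, X.shape[0], batch_size)]
        return np.vstack(out) if out else np.empty((0, self.config.bottleneck_dim))

    # -- checkpointing ----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "config": {
                "input_dim": self.config.input_dim,
                "hidden_widths": list(self.config.hidden_widths),
                "bottleneck_dim": self.config.bottleneck_dim,
                "goi_head_hidden": list(self.config.goi_head_hidden),
                "activation": self.config.activation,
                "celu_alpha": self.config.celu_alpha,
            },
            "goi_spec": self.goi_spec.to_text(),
        }
        arrays = {}
        for part_name, part in (
            ("enc", self.encoder), ("dec", self.decoder), ("goi", self.goi_head)
        ):
            for i, lin in enumerate(part.linears()):
                arrays[f"{part_name}_{i}_W"] = lin.W
                arrays[f"{part_name}_{i}_b"] = lin.b
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "SakuraModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValidationError(f"unknown checkpoint schema {meta.get('schema')!r}")
            npz = np.load(io.BytesIO(zf.read("params.npz")))
        cfg = meta["config"]
        config = ModelConfig(
            input_dim=cfg["input_dim"],
            hidden_widths=tuple(cfg["hidden_widths"]),
            bottleneck_dim=cfg["bottleneck_dim"],
            goi_head_hidden=tuple(cfg["goi_head_hidden"]),
            activation=cfg["activation"],
            celu_alpha=cfg["celu_alpha"],
        )
        model = cls(config, GOISpec.parse(meta["goi_spec"]))
        for part_name, part in (
            ("enc", model.encoder), ("dec", model.decoder), ("goi", model.goi_head)
        ):
            for i, lin in enumerate(part.linears()):
                lin.W = npz[f"{part_name}_{i}_W"]
                lin.b = npz[f"{part_name}_{i}_b"]
        return model

    # -- optimizers -------------------------------------------------------
    def make_optimizers(self, lr: float, alpha: float) -> tuple[RMSProp, RMSProp]:
        """(rec+reg-step optimizer over enc+dec, GOI-step optimizer over
        enc+head).

        The encoder appears in both optimizers with separate smoothing
        state per objective: each objective's steps stay at their natural
        RMSProp scale, so the 5-target GOI gradient is not drowned by the
        much larger reconstruction gradient.
        """
        opt_rec = RMSProp(self.encoder.params() + self.decoder.params(), lr, alpha)
        opt_goi = RMSProp(self.encoder.params() + self.goi_head.params(), lr, alpha)
        return opt_rec, opt_goi


# ---------------------------------------------------------------------------
# losses (values follow the sum-over-cells convention; gradient helpers
# return d(loss)/d(prediction) for the same convention)
# ---------------------------------------------------------------------------

def reconstruction_loss(
    x: np.ndarray, x_rec: np.ndarray, w: LossWeights,
    return_grad: bool = False,
):
    """Sum over cells of lambda1 * |x - x'|_1 + lambda2 * |x - x'|_2^2."""
    x = np.asarray(x, dtype=np.float64)
    x_rec = np.asarray(x_rec, dtype=np.float64)
    if x.shape != x_rec.shape:
        raise ValidationError("x and x_rec shapes differ")
    d = x - x_rec
    value = w.lambda1 * np.abs(d).sum() + w.lambda2 * (d * d).sum()
    if not return_grad:
        return value
    grad = -w.lambda1 * np.sign(d) - 2.0 * w.lambda2 * d
    return value, grad


def goi_loss(
    y: np.ndarray, y_pred: np.ndarray, w: LossWeights,
    return_grad: bool = False,
):
    """GOI regression loss combining L1, squared L2, and cosine distance.

    The cosine term is computed once per cell over the cell's T-dimensional
    target vector (for T = 1 it reduces to a sign-agreement penalty). An
    epsilon guard of 1e-8 on each norm handles zero vectors; a cell whose
    true and predicted vectors are both all-zero contributes 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=np.float64))
    if y.shape != y_pred.shape:
        raise ValidationError("y and y_pred shapes differ")
    d = y - y_pred
    value = w.lambda4 * np.abs(d).sum() + w.lambda5 * (d * d).sum()
    ny = np.linalg.norm(y, axis=1)
    np_ = np.linalg.norm(y_pred, axis=1)
    dot = (y * y_pred).sum(axis=1)
    denom = (ny + COSINE_EPS) * (np_ + COSINE_EPS)
    cos = dot / denom
    both_zero = (ny == 0) & (np_ == 0)
    cos_term = np.where(both_zero, 0.0, 1.0 - cos)
    value = value + w.lambda6 * cos_term.sum()
    if not return_grad:
        return float(value)
    grad = -w.lambda4 * np.sign(d) - 2.0 * w.lambda5 * d
    if w.lambda6 > 0:
        # d(1 - cos)/d y_pred = -( y / denom - dot * unit(y_pred) * ny_eps / denom^2 )
        unit_pred = y_pred / (np_ + COSINE_EPS)[:, None]
        gcos = -(
            y / denom[:, None]
            - (dot / denom**2 * (ny + COSINE_EPS))[:, None] * unit_pred
        )
        gcos[both_zero] = 0.0
        grad = grad + w.lambda6 * gcos
    return float(value), grad


def total_loss(rec: float, reg: float, goi: float) -> float:
    """Overall loss: plain sum of the three components."""
    return rec + reg + goi
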