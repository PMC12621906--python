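"""Training loop: alternating two-pass updates, ramp-up schedules, canary
diagnostics, and the regularization-inclusion decision procedure.

Each epoch first updates encoder + decoder for the reconstruction and
regularization losses (batches of 200 cells), then updates encoder + GOI
head for the GOI regression loss (batches of 100 cells; the decoder is
frozen during this pass). Loss-weight ramp-up delays supervision: the
regularization weight lambda3 starts at 1e-4 and grows by 0.01 per epoch
(cap 1); the GOI weights lambda4..6 stay 0 for the first 50 epochs, then
grow by 0.01 per epoch (cap 1). Training uses a random 50/50 train/test
split, with the test half serving as a canary for abnormal behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ValidationError
from .model import (
    LossWeights,
    ModelConfig,
    SakuraModel,
    goi_loss,
    reconstruction_loss,
    total_loss,
)
from .regularize import PriorSpec, reg_loss, sliced_w2


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lambda3Schedule:
    """Ramp-up of the regularization weight: init + increment * epoch, capped.

    ``multiplicative=True`` switches to init * (1 + increment) ** epoch.
    """

    init: float = 1e-4
    increment: float = 0.01
    cap: float = 1.0
    multiplicative: bool = False


@dataclass(frozen=True)
class Lambda456Schedule:
    """GOI-weight ramp-up: zero before ``start_epoch`` (0-based), then
    ``increment * (epoch - start_epoch + 1)`` capped at ``cap``."""

    start_epoch: int = 50
    increment: float = 0.01
    cap: float = 1.0


def lambda_schedule(epoch: int, schedule) -> float:
    """Evaluate a ramp-up schedule at a (0-based) epoch index."""
    if epoch < 0:
        raise ValidationError("epoch must be >= 0")
    if isinstance(schedule, Lambda3Schedule):
        if schedule.multiplicative:
            return float(min(schedule.cap, schedule.init * (1 + schedule.increment) ** epoch))
        return float(min(schedule.cap, schedule.init + schedule.increment * epoch))
    if isinstance(schedule, Lambda456Schedule):
        if epoch < schedule.start_epoch:
            return 0.0
        return float(
            min(schedule.cap, schedule.increment * (epoch - schedule.start_epoch + 1))
        )
    raise ValidationError(f"unknown schedule type {type(schedule).__name__}")


# ---------------------------------------------------------------------------
# configuration / state
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 300
    batch_rec: int = 200
    batch_goi: int = 100
    lr: float = 0.001
    rmsprop_alpha: float = 0.9
    seed: int = 0
    split_fraction: float = 0.5
    schedule_l3: Lambda3Schedule = field(default_factory=Lambda3Schedule)
    schedule_l456: Lambda456Schedule = field(default_factory=Lambda456Schedule)
    goi_multiplier: float = 1.0   # scalar multiplier on the lambda4..6 caps
    use_reg: bool = True
    use_goi: bool = True
    reg_n_slices: int = 50
    reg_k: float = 5.0
    reg_squared: bool = False
    early_stop_tol: float = 1e-5
    early_stop_patience: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValidationError("split_fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


@dataclass
class TrainingState:
    """Per-epoch loss/weight history plus a reference to the model."""

    model: SakuraModel
    history: dict[str, list] = field(default_factory=dict)
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def record(self, **kv) -> None:
        for key, val in kv.items():
            self.history.setdefault(key, []).append(val)

    def last(self, key: str) -> float:
        return self.history[key][-1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def split_cells(
    n_cells: int, fraction: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive train/test split of cell indices.

    Train size is ``floor(fraction * M)``; the remainder is the test set.
    """
    if n_cells < 2:
        raise ValidationError("need at least 2 cells to split")
    if not (0 < fraction < 1):
        raise ValidationError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_cells)
    n_train = int(np.floor(fraction * n_cells))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _epoch_rngs(seed: int, epoch: int):
    children = np.random.SeedSequence([seed & 0x7FFFFFFF, epoch]).spawn(3)
    return (
        np.random.default_rng(children[0]),  # rec shuffling
        np.random.default_rng(children[1]),  # goi shuffling
        np.random.default_rng(children[2]),  # reg prior / slices
    )


def _check_finite(value: float, component: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite {component} loss at epoch {epoch}: {value}"
        )


def train_epoch(
    state: TrainingState,
    X_train: np.ndarray,
    Y_train: np.ndarray | None,
    config: TrainConfig,
    epoch: int,
    opt_rec,
    opt_goi,
    prior: PriorSpec,
    weights: LossWeights,
) -> dict[str, float]:
    """One epoch: a rec+reg pass then (if any GOI weight is active) a GOI pass.

    Returns the per-cell mean training losses of the epoch. Deterministic
    given ``config.seed`` and ``epoch``.
    """
    model = state.model
    n = X_train.shape[0]
    rng_rec, rng_goi, rng_reg = _epoch_rngs(config.seed, epoch)

    lam3 = lambda_schedule(epoch, config.schedule_l3) if config.use_reg else 0.0
    lam456 = lambda_schedule(epoch, config.schedule_l456) * config.goi_multiplier
    if not config.use_goi or Y_train is None:
        lam456 = 0.0
    w = replace(weights, lambda3=lam3, lambda4=lam456 * weights.lambda4,
                lambda5=lam456 * weights.lambda5, lambda6=lam456 * weights.lambda6)

    rec_sum = reg_sum = 0.0
    order = rng_rec.permutation(n)
    n_batches = 0
    for start in range(0, n, config.batch_rec):
        idx = order[start:start + config.batch_rec]
        xb = X_train[idx]
        h = model.encoder.forward(xb)
        x_rec = model.decoder.forward(h)
        rec_val, g_rec = reconstruction_loss(xb, x_rec, w, return_grad=True)
        _check_finite(rec_val, "reconstruction", epoch)
        g_h = model.decoder.backward(g_rec / len(idx))
        if lam3 > 0:
            batch_seed = int(rng_reg.integers(0, 2**31 - 1))
            reg_val, g_reg = reg_loss(
                h, prior, lam3, config.reg_n_slices, batch_seed,
                squared=config.reg_squared, return_grad=True,
            )
            _check_finite(reg_val, "regularization", epoch)
            g_h = g_h + g_reg
            reg_sum += reg_val
        model.encoder.backward(g_h)
        opt_rec.step()
        rec_sum += rec_val
        n_batches += 1

    goi_sum = 0.0
    if lam456 > 0:
        order = rng_goi.permutation(n)
        for start in range(0, n, config.batch_goi):
            idx = order[start:start + config.batch_goi]
            xb = X_train[idx]
            yb = Y_train[idx]
            h = model.encoder.forward(xb)
            y_pred = model.goi_head.forward(h)
            goi_val, g_goi = goi_loss(yb, y_pred, w, return_grad=True)
            _check_finite(goi_val, "goi", epoch)
            g_h = model.goi_head.backward(g_goi / len(idx))
            model.encoder.backward(g_h)  # decoder frozen during the GOI pass
            opt_goi.step()
            goi_sum += goi_val

    return {
        "lambda3": lam3,
        "lambda456": lam456,
        "rec_train": rec_sum / n,
        "reg_train": reg_sum / max(n_batches, 1),
        "goi_train": goi_sum / n,
    }


def _eval_losses(model, X, Y, w, prior, config, seed):
    h = model.embed(X)
    x_rec = model.decoder.forward(h)
    rec = reconstruction_loss(X, x_rec, w) / X.shape[0]
    reg = 0.0
    if w.lambda3 > 0:
        reg = reg_loss(h, prior, w.lambda3, config.reg_n_slices, seed,
                       squared=config.reg_squared)
    goi = 0.0
    if Y is not None and (w.lambda4 or w.lambda5 or w.lambda6):
        y_pred = model.goi_head.forward(h)
        goi = goi_loss(Y, y_pred, w) / X.shape[0]
    return rec, reg, goi


def fit(
    X_scaled: np.ndarray,
    goi_targets: np.ndarray | None,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    goi_spec=None,
    weights: LossWeights | None = None,
    log_path=None,
) -> TrainingState:
    """Train a model on a scaled matrix with precomputed GOI targets.

    Splits cells 50/50 (``config.split_fraction``), trains on the first
    half, and records per-epoch train/test loss components. Early-stops
    when the total training loss improves by less than ``early_stop_tol``
    (relatively) for ``early_stop_patience`` consecutive epochs.
    """
    from .model import GOISpec, GOITarget  # local to avoid import cycle noise

    X_scaled = np.asarray(X_scaled, dtype=np.float64)
    m, n_genes = X_scaled.shape
    weights = weights or LossWeights()
    if goi_spec is None:
        n_targets = goi_targets.shape[1] if goi_targets is not None else 1
        goi_spec = GOISpec(
            [GOITarget(f"t{j}", "gene", (f"t{j}",)) for j in range(n_targets)]
        )
    if model_config is None:
        model_config = ModelConfig(input_dim=n_genes)

    train_idx, test_idx = split_cells(m, config.split_fraction, config.seed)
    model = SakuraModel(model_config, goi_spec, seed=config.seed)
    state = TrainingState(model=model, train_idx=train_idx, test_idx=test_idx)
    opt_rec, opt_goi = model.make_optimizers(config.lr, config.rmsprop_alpha)
    prior = PriorSpec(k=config.reg_k, dims=model_config.bottleneck_dim)

    X_train, X_test = X_scaled[train_idx], X_scaled[test_idx]
    Y_train = Y_test = None
    if goi_targets is not None:
        goi_targets = np.asarray(goi_targets, dtype=np.float64)
        Y_train, Y_test = goi_targets[train_idx], goi_targets[test_idx]

    log_fh = open(log_path, "w") if log_path else None
    if log_fh:
        log_fh.write("epoch\tlambda3\tlambda456\trec_train\trec_test\treg\t"
                     "goi_train\tgoi_test\ttotal_train\ttotal_test\n")
    # ramp-up makes the total loss non-stationary; only count early-stop
    # patience once every schedule has reached its cap
    cap3 = (
        0 if config.schedule_l3.increment == 0
        else int(np.ceil((config.schedule_l3.cap - config.schedule_l3.init)
                         / config.schedule_l3.increment))
    )
    cap456 = (
        config.schedule_l456.start_epoch
        + (0 if config.schedule_l456.increment == 0
           else int(np.ceil(config.schedule_l456.cap / config.schedule_l456.increment)))
    )
    ramp_done = max(cap3 if config.use_reg else 0,
                    cap456 if config.use_goi else 0)
    best = np.inf
    stall = 0
    try:
        for epoch in range(config.epochs):
            stats = train_epoch(state, X_train, Y_train, config, epoch,
                                opt_rec, opt_goi, prior, weights)
            lam456 = stats["lambda456"]
            w_eval = replace(
                weights, lambda3=stats["lambda3"],
                lambda4=lam456 * weights.lambda4,
                lambda5=lam456 * weights.lambda5,
                lambda6=lam456 * weights.lambda6,
            )
            eval_seed = int(
                np.random.SeedSequence([config.seed & 0x7FFFFFFF, epoch, 7]).generate_state(1)[0]
                % (2**31)
            )
            rec_te, reg_te, goi_te = _eval_losses(
                model, X_test, Y_test, w_eval, prior, config, eval_seed
            )
            tot_tr = total_loss(stats["rec_train"], stats["reg_train"], stats["goi_train"])
            tot_te = total_loss(rec_te, reg_te, goi_te)
            state.record(epoch=epoch, lambda3=stats["lambda3"], lambda456=lam456,
                         rec_train=stats["rec_train"], rec_test=rec_te,
                         reg_train=stats["reg_train"], reg_test=reg_te,
                         goi_train=stats["goi_train"], goi_test=goi_te,
                         total_train=tot_tr, total_test=tot_te)
            if log_fh:
                log_fh.write(
                    f"{epoch}\t{stats['lambda3']:.6g}\t{lam456:.6g}\t"
                    f"{stats['rec_train']:.6g}\t{rec_te:.6g}\t{stats['reg_train']:.6g}\t"
                    f"{stats['goi_train']:.6g}\t{goi_te:.6g}\t{tot_tr:.6g}\t{tot_te:.6g}\n"
                )
            if epoch < ramp_done:
                continue
            if tot_tr < best * (1 - config.early_stop_tol):
                best = tot_tr
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    break
    finally:
        if log_fh:
            log_fh.close()
    return state


def embed_all(model: SakuraModel, X_scaled: np.ndarray) -> np.ndarray:
    """Encoder applied to every cell, train and test alike."""
    return model.embed(np.asarray(X_scaled, dtype=np.float64))


# ---------------------------------------------------------------------------
# canary diagnostics
# ---------------------------------------------------------------------------

def canary_check(
    state: TrainingState,
    train_embedding: np.ndarray,
    test_embedding: np.ndarray,
    gap_threshold: float = 0.5,
    sw2_factor: float = 3.0,
    n_slices: int = 50,
    seed: int = 0,
    n_resamples: int = 5,
) -> dict:
    """Compare train and test behavior to detect training pathologies.

    Reports (a) the relative gap between final train and test total loss
    and (b) the sliced-W2 distance between the train and test embedding
    clouds against a self-distance baseline from resampled train halves.
    """
    tot_tr = state.last("total_train")
    tot_te = state.last("total_test")
    gap = abs(tot_tr - tot_te) / max(abs(tot_tr), 1e-12)

    sw = sliced_w2(train_embedding, test_embedding, n_slices, seed)
    rng = np.random.default_rng(seed)
    baselines = []
    n = train_embedding.shape[0]
    for r in range(n_resamples):
        perm = rng.permutation(n)
        half = n // 2
        baselines.append(
            sliced_w2(train_embedding[perm[:half]], train_embedding[perm[half:2 * half]],
                      n_slices, int(rng.integers(0, 2**31 - 1)))
        )
    baseline = float(np.mean(baselines))
    flagged = bool(gap > gap_threshold or sw > sw2_factor * max(baseline, 1e-12))
    return {
        "loss_gap": float(gap),
        "sw2_train_test": float(sw),
        "sw2_self_baseline": baseline,
        "gap_threshold": gap_threshold,
        "sw2_factor": sw2_factor,
        "flagged": flagged,
    }


# ---------------------------------------------------------------------------
# regularization decision procedure
# ---------------------------------------------------------------------------

def choose_by_cluster_counts(
    baseline_k: int, with_reg_k: int, without_reg_k: int
) -> str:
    """Pick the variant whose cluster count is closer to the baseline's.

    The regularized variant wins ties.
    """
    if abs(with_reg_k - baseline_k) <= abs(without_reg_k - baseline_k):
        return "with_reg"
    return "without_reg"


def decide_regularization(
    X_scaled: np.ndarray,
    goi_targets: np.ndarray | None,
    config: TrainConfig,
    baseline_embedding: np.ndarray,
    model_config: ModelConfig | None = None,
    goi_spec=None,
    cluster_kwargs: dict | None = None,
) -> tuple[TrainingState, dict]:
    """Train with and without the regularization loss and keep the variant
    whose Louvain cluster count is closer to the PCA-baseline count."""
    from .cluster import snn_graph_cluster

    cluster_kwargs = dict(cluster_kwargs or {})
    cluster_kwargs.setdefault("seed", config.seed)

    base_assign = snn_graph_cluster(baseline_embedding, **cluster_kwargs)
    state_with = fit(X_scaled, goi_targets, replace(config, use_reg=True),
                     model_config, goi_spec)
    state_without = fit(X_scaled, goi_targets, replace(config, use_reg=False),
                        model_config, goi_spec)
    k_with = snn_graph_cluster(embed_all(state_with.model, X_scaled), **cluster_kwargs).k
    k_without = snn_graph_cluster(
        embed_all(state_without.model, X_scaled), **cluster_kwargs
    ).k
    choice = choose_by_cluster_counts(base_assign.k, k_with, k_without)
    record = {
        "baseline_k": base_assign.k,
        "with_reg_k": k_with,
        "without_reg_k": k_without,
        "choice": choice,
    }
    chosen = state_with if choice == "with_reg" else state_without
    return chosen, record
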