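"""Sliced 2-Wasserstein regularization toward a uniform latent prior.

The regularizer compares the empirical distribution of a batch of cell
embeddings with samples from a predefined prior, by projecting both onto
random one-dimensional slices and averaging the squared 1-D Wasserstein-2
distances between the projected samples. A uniform prior over a hypercube
``(-k, k)^d`` spreads the embedding over the latent space and prevents
representation collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ValidationError

DEFAULT_N_SLICES = 50
DEFAULT_K = 5.0


@dataclass
class PriorSpec:
    """Uniform prior over ``(-k, k)^dims``."""

    k: float = DEFAULT_K
    dims: int = 50
    kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError("prior bound k must be positive")
        if self.kind != "uniform":
            raise ValidationError(f"unsupported prior kind {self.kind!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-self.k, self.k, size=(n, self.dims))


def _unit_directions(d: int, n_slices: int, rng: np.random.Generator) -> np.ndarray:
    """``(d, n_slices)`` columns uniform on the (d-1)-sphere."""
    theta = rng.standard_normal((d, n_slices))
    norms = np.linalg.norm(theta, axis=0)
    norms[norms == 0] = 1.0
    return theta / norms


def sliced_w2(
    A: np.ndarray,
    B: np.ndarray,
    n_slices: int = DEFAULT_N_SLICES,
    seed: int = 0,
    return_grad_A: bool = False,
):
    """Sliced 2-Wasserstein distance between two equal-size samples.

    Projects both samples onto ``n_slices`` random unit directions (seeded),
    matches order statistics on each slice, and returns the square root of
    the mean per-slice squared W2 (the metric convention). If sample counts
    differ, ``B`` is resampled with replacement to match ``A``.

    With ``return_grad_A`` the gradient of the distance with respect to the
    rows of ``A`` is also returned (used inside the training loop).
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    n, d = A.shape
    if n == 0 or B.shape[0] == 0:
        raise ValidationError("empty sample passed to sliced_w2")
    if B.shape[1] != d:
        raise ValidationError("A and B must have the same dimensionality")
    rng = np.random.default_rng(seed)
    theta = _unit_directions(d, n_slices, rng)
    if B.shape[0] != n:
        B = B[rng.integers(0, B.shape[0], size=n)]

    PA = A @ theta  # (n, S)
    PB = B @ theta
    order_A = np.argsort(PA, axis=0, kind="stable")
    sA = np.take_along_axis(PA, order_A, axis=0)
    sB = np.sort(PB, axis=0)
    diffs = sA - sB
    mean_sq = float((diffs**2).mean())  # mean over both n and slices
    value = float(np.sqrt(mean_sq))
    if not return_grad_A:
        return value
    # d(mean_sq)/d sA = 2 * diffs / (n * S); scatter back through the sort,
    # then chain through the projection and the square root.
    g_sorted = 2.0 * diffs / diffs.size
    gPA = np.empty_like(g_sorted)
    np.put_along_axis(gPA, order_A, g_sorted, axis=0)
    gA = gPA @ theta.T
    if value > 0:
        gA = gA / (2.0 * value)
    else:
        gA = np.zeros_like(gA)
    return value, gA


def reg_loss(
    embedding: np.ndarray,
    prior: PriorSpec,
    lambda3: float,
    n_slices: int = DEFAULT_N_SLICES,
    seed: int = 0,
    squared: bool = False,
    return_grad: bool = False,
):
    """``lambda3 * SW2(embedding, prior sample)`` (optionally squared).

    A fresh prior sample of the batch size is drawn with the given seed, so
    the regularization is stochastic but reproducible.
    """
    embedding = np.atleast_2d(np.asarray(embedding, dtype=np.float64))
    if prior.dims != embedding.shape[1]:
        raise ValidationError(
            f"prior dims {prior.dims} != embedding dims {embedding.shape[1]}"
        )
    if lambda3 < 0:
        raise ValidationError("lambda3 must be non-negative")
    if lambda3 == 0:
        if return_grad:
            return 0.0, np.zeros_like(embedding)
        return 0.0
    rng = np.random.default_rng(seed)
    target = prior.sample(embedding.shape[0], rng)
    slice_seed = int(rng.integers(0, 2**31 - 1))
    sw, grad = sliced_w2(embedding, target, n_slices, slice_seed, return_grad_A=True)
    if squared:
        value = lambda3 * sw * sw
        grad = lambda3 * 2.0 * sw * grad
    else:
        value = lambda3 * sw
        grad = lambda3 * grad
    if return_grad:
        return float(value), grad
    return float(value)
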