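"""Exact t-SNE dimensionality reduction of feature matrices.

High-dimensional backbone features are mapped to a fixed lower
dimension per backbone (DenseNet121 -> 724, MobileNet -> 694,
VGG19 -> 921 columns) before classification.  The reduction is plain
(non-accelerated) t-SNE: Gaussian affinities in the input space with
per-point bandwidths found by bisection on the perplexity, Student-t
affinities in the embedding, and gradient descent on their KL
divergence with momentum and early exaggeration.  Tree-based
accelerations only help for 2-3 output dimensions, far below the
target dimensions here, so the exact gradient is used.

Because an embedding of the *samples* and a selection of the original
*columns* are both defensible readings of "reduce the features",
:func:`reduce_features` offers two modes: ``embed`` (default; the
output matrix shapes match the published ones) and ``select`` (keep
the ``d`` highest-variance original columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import FeatureMatrix

__all__ = [
    "TSNEParams",
    "REDUCTION_DIMS",
    "pairwise_affinities",
    "kl_divergence",
    "tsne_reduce",
    "reduce_features",
]

#: Backbone name -> target feature dimension after reduction.
REDUCTION_DIMS: dict[str, int] = {
    "densenet121": 724,
    "mobilenet": 694,
    "vgg19": 921,
    "toy": 32,
}

_EPS = 1e-12


@dataclass(frozen=True)
class TSNEParams:
    """t-SNE hyperparameters.

    ``out_dim`` is the embedding dimension d (1 <= d < p);
    ``perplexity`` the effective neighbor count (must be < n);
    early exaggeration multiplies P by ``early_exaggeration`` for the
    first ``exaggeration_iter`` iterations; momentum switches from
    ``momentum`` to ``final_momentum`` at ``momentum_switch_iter``.
    """

    out_dim: int = 2
    perplexity: float = 30.0
    learning_rate: float = 200.0
    momentum: float = 0.5
    final_momentum: float = 0.8
    momentum_switch_iter: int = 250
    iterations: int = 500
    early_exaggeration: float = 12.0
    exaggeration_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_dim < 1:
            raise ValueError("out_dim must be >= 1")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _entropy_and_probs(dist_row: np.ndarray, beta: float) -> tuple[float, np.ndarray]:
    """Shannon entropy (nats) and conditional probabilities for one point.

    ``beta = 1 / (2 sigma^2)``; ``dist_row`` holds squared distances to
    every other point (self excluded by the caller).
    """
    logits = -dist_row * beta
    logits -= logits.max()
    p = np.exp(logits)
    s = p.sum()
    if s <= 0:
        return 0.0, np.full_like(dist_row, 1.0 / max(len(dist_row), 1))
    p /= s
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return h, p


def pairwise_affinities(
    X: FeatureMatrix | np.ndarray,
    perplexity: float = 30.0,
    tol: float = 1e-3,
    max_bisect: int = 100,
    return_sigmas: bool = False,
):
    """Symmetrized Gaussian affinity matrix P with per-point bandwidths.

    Each point's sigma_i is found by bisection (on beta = 1/(2 sigma^2))
    so the entropy of its conditional distribution equals
    ``log(perplexity)`` within ``tol``.  Conditionals are symmetrized,
    ``P = (P_cond + P_cond^T) / (2n)``, giving a symmetric matrix with
    zero diagonal summing to 1.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    n = Xv.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n ({n})")
    target = np.log(perplexity)
    D = squareform(pdist(Xv, "sqeuclidean"))
    cond = np.zeros((n, n))
    sigmas = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        row = D[i, idx != i]
        if row.max() <= 0:
            raise ValueError(
                f"point {i} has zero distance to all others; bandwidth "
                "bisection cannot bracket a solution"
            )
        beta, lo, hi = 1.0, 0.0, np.inf
        h, p = _entropy_and_probs(row, beta)
        for _ in range(max_bisect):
            if abs(h - target) <= tol:
                break
            if h > target:  # too entropic -> narrow the kernel
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (beta + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
            h, p = _entropy_and_probs(row, beta)
        cond[i, idx != i] = p
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    P = (cond + cond.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    P /= P.sum()
    return (P, sigmas) if return_sigmas else P


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """KL(P || Q) = sum P log(P/Q); zero-P terms contribute nothing."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    mask = P > 0
    return float((P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))).sum())


def _student_t_affinities(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Q matrix and unnormalized weights W = 1/(1+||y_i-y_j||^2)."""
    D = squareform(pdist(Y, "sqeuclidean"))
    W = 1.0 / (1.0 + D)
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    return np.maximum(Q, _EPS), W


def tsne_reduce(
    X: FeatureMatrix | np.ndarray,
    params: TSNEParams | None = None,
    return_trace: bool = False,
):
    """Embed the rows of X into ``out_dim`` coordinates by exact t-SNE.

    Gradient descent on KL(P || Q) with the standard gradient
    ``4 * sum_j (p_ij - q_ij) w_ij (y_i - y_j)``, momentum, and early
    exaggeration.  Deterministic given ``params.seed``.  Returns a
    :class:`FeatureMatrix` (row order preserved); with
    ``return_trace=True`` also the KL objective per iteration
    (computed against the un-exaggerated P).
    """
    params = params or TSNEParams()
    fm = X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X))
    n, p = fm.shape
    if not 1 <= params.out_dim < p:
        raise ValueError(f"out_dim must satisfy 1 <= d < p={p}")
    P = pairwise_affinities(fm.values, params.perplexity)
    rng = np.random.default_rng(params.seed)
    Y = rng.normal(0.0, 1e-4, size=(n, params.out_dim))
    velocity = np.zeros_like(Y)
    trace: list[float] = []
    for it in range(params.iterations):
        exaggerate = it < params.exaggeration_iter
        P_eff = P * params.early_exaggeration if exaggerate else P
        Q, W = _student_t_affinities(Y)
        S = (P_eff - Q) * W
        grad = 4.0 * ((np.diag(S.sum(axis=1)) - S) @ Y)
        momentum = (
            params.momentum
            if it < params.momentum_switch_iter
            else params.final_momentum
        )
        velocity = momentum * velocity - params.learning_rate * grad
        Y = Y + velocity
        Y -= Y.mean(axis=0)
        if not np.all(np.isfinite(Y)):
            raise FloatingPointError(f"embedding diverged at iteration {it}")
        trace.append(kl_divergence(P, Q))
    out = FeatureMatrix(Y, list(fm.row_ids))
    return (out, np.asarray(trace)) if return_trace else out


def reduce_features(
    F: FeatureMatrix,
    backbone_name: str,
    mode: str = "embed",
    seed: int = 0,
    params: TSNEParams | None = None,
) -> FeatureMatrix:
    """Reduce a backbone feature matrix to its registry dimension.

    ``mode='embed'`` runs t-SNE to d = registry dimension; with more
    target dimensions than samples this is capped at n - 1 (an n-point
    embedding spans at most n - 1 directions) and zero-padded back to
    the registry width so downstream fusion arithmetic still sees the
    declared column counts.  ``mode='select'`` instead keeps the d
    original columns with the highest variance.  Row order is
    preserved either way.
    """
    name = backbone_name.lower()
    if name not in REDUCTION_DIMS:
        raise KeyError(f"unknown backbone {backbone_name!r}; known: {sorted(REDUCTION_DIMS)}")
    d = REDUCTION_DIMS[name]
    if d >= F.p:
        raise ValueError(
            f"registry dimension {d} must be smaller than source dimension {F.p}"
        )
    if mode == "select":
        variances = F.values.var(axis=0)
        keep = np.sort(np.argsort(variances)[::-1][:d])
        return FeatureMatrix(F.values[:, keep], list(F.row_ids))
    if mode != "embed":
        raise ValueError("mode must be 'embed' or 'select'")
    d_eff = min(d, F.n - 1)
    base = params or TSNEParams()
    pp = min(base.perplexity, max((F.n - 1) / 3.0, 2.0))
    eff = TSNEParams(
        out_dim=d_eff,
        perplexity=pp,
        learning_rate=base.learning_rate,
        momentum=base.momentum,
        final_momentum=base.final_momentum,
        momentum_switch_iter=base.momentum_switch_iter,
        iterations=base.iterations,
        early_exaggeration=base.early_exaggeration,
        exaggeration_iter=base.exaggeration_iter,
        seed=seed,
    )
    emb = tsne_reduce(F, eff)
    if d_eff < d:
        padded = np.zeros((F.n, d))
        padded[:, :d_eff] = emb.values
        return FeatureMatrix(padded, list(F.row_ids))
    return emb
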