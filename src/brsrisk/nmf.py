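"""Nonnegative matrix factorization V ~ W H by multiplicative updates.

The factorization minimizes the Frobenius reconstruction error
``||V - W H||_F`` over elementwise-nonnegative W (rows x d) and H (d x cols)
with the classic multiplicative update rules

    H <- H * (W' V) / (W' W H + eps)
    W <- W * (V H') / (W H H' + eps)

which never increase the objective. ``d`` is the number of latent variables;
columns of W serve as per-patient latent features downstream. Multiple random
restarts guard against poor local minima; the held-out projection re-solves
for W with H frozen so cross-validation folds never touch each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._base import BaseEstimator, DomainError, check_is_fitted

__all__ = [
    "FactorizationResult",
    "minmax_scale",
    "nmf_fit",
    "nmf_project",
    "LatentNMF",
]

logger = logging.getLogger(__name__)

_EPS = 1e-10


def minmax_scale(X) -> np.ndarray:
    """Map each column affinely onto [0, 1]; constant columns map to zeros."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise DomainError("minmax_scale requires finite entries")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    span = maxs - mins
    out = np.zeros_like(X, dtype=float)
    nz = span > 0
    out[:, nz] = (X[:, nz] - mins[nz]) / span[nz]
    return out


@dataclass(frozen=True)
class FactorizationResult:
    """Fitted nonnegative factors and their optimization trace."""

    W: np.ndarray  # rows x d, >= 0
    H: np.ndarray  # d x cols, >= 0
    d: int
    objective_trace: np.ndarray  # Frobenius loss per iteration, nonincreasing
    seed: int
    n_iter: int
    converged: bool

    @property
    def reconstruction_error(self) -> float:
        return float(self.objective_trace[-1])


def _frobenius(V, W, H) -> float:
    return float(np.linalg.norm(V - W @ H))


def _init_factors(V, d, rng):
    scale = np.sqrt(max(V.mean(), _EPS) / d)
    W = rng.uniform(0.0, 1.0, size=(V.shape[0], d)) * scale
    H = rng.uniform(0.0, 1.0, size=(d, V.shape[1])) * scale
    return W, H


def _mu_iterate(V, W, H, max_iter, tol, update_h=True):
    """Run multiplicative updates; returns (W, H, trace, n_iter, converged)."""
    trace = [_frobenius(V, W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if update_h:
            H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        loss = _frobenius(V, W, H)
        prev = trace[-1]
        trace.append(loss)
        if prev - loss < tol * max(prev, _EPS):
            converged = True
            break
    return W, H, np.asarray(trace), it, converged


def _normalize_scale(W, H):
    """Resolve the diagonal scale indeterminacy: each row of H gets unit max.

    W is rescaled inversely so the product W H is unchanged (to round-off).
    All-zero H rows are left untouched.
    """
    hmax = H.max(axis=1)
    nz = hmax > 0
    H[nz] /= hmax[nz, None]
    W[:, nz] *= hmax[nz]
    return W, H


def nmf_fit(
    V,
    d: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
    seed: int = 0,
) -> FactorizationResult:
    """Best-of-``n_restarts`` multiplicative-update NMF of a nonnegative matrix.

    Entries of W and H initialize as ``Uniform(0,1) * sqrt(mean(V)/d)``;
    restart ``k`` uses seed ``seed + k``, so identical arguments are
    bit-reproducible. Iteration stops when the relative objective decrease
    falls below ``tol`` or after ``max_iter`` iterations. ``d`` larger than
    both matrix dimensions is permitted (over-complete) but logged.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise DomainError("V must be a 2-d matrix")
    if (V < 0).any():
        raise DomainError("V must be elementwise nonnegative")
    if d < 1:
        raise DomainError(f"d must be >= 1, got {d}")
    if d > min(V.shape):
        logger.info("nmf_fit: over-complete d=%d for shape %s", d, V.shape)

    if not V.any():
        # all-zero matrix: the zero factorization is exact
        return FactorizationResult(
            W=np.zeros((V.shape[0], d)),
            H=np.zeros((d, V.shape[1])),
            d=d,
            objective_trace=np.array([0.0]),
            seed=seed,
            n_iter=0,
            converged=True,
        )

    best = None
    for k in range(n_restarts):
        restart_seed = int((seed + k) % (2**31))
        rng = np.random.default_rng(restart_seed)
        W, H = _init_factors(V, d, rng)
        W, H, trace, n_iter, converged = _mu_iterate(V, W, H, max_iter, tol)
        if best is None or trace[-1] < best.objective_trace[-1]:
            W, H = _normalize_scale(W, H)
            best = FactorizationResult(
                W=W,
                H=H,
                d=d,
                objective_trace=trace,
                seed=restart_seed,
                n_iter=n_iter,
                converged=converged,
            )
    return best


def nmf_project(
    H,
    V_new,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Latent scores for new rows under a frozen loading matrix H.

    Solves ``min_W ||V_new - W H||_F`` over W >= 0 by multiplicative updates
    on W only — the convex subproblem — so held-out subjects are embedded
    without refitting H (no information flows back into the training factors).
    """
    H = np.asarray(H, dtype=float)
    V_new = np.asarray(V_new, dtype=float)
    if V_new.ndim != 2 or H.ndim != 2:
        raise DomainError("H and V_new must be 2-d matrices")
    if V_new.shape[1] != H.shape[1]:
        raise DomainError(
            f"column mismatch: V_new has {V_new.shape[1]} columns, "
            f"H expects {H.shape[1]}"
        )
    if (V_new < 0).any():
        raise DomainError("V_new must be elementwise nonnegative")
    if not H.any() or not V_new.any():
        return np.zeros((V_new.shape[0], H.shape[0]))
    rng = np.random.default_rng(int(seed % (2**31)))
    scale = np.sqrt(max(V_new.mean(), _EPS) / H.shape[0])
    W = rng.uniform(0.0, 1.0, size=(V_new.shape[0], H.shape[0])) * scale
    W, _, _, _, _ = _mu_iterate(V_new, W, H.copy(), max_iter, tol, update_h=False)
    return W


class LatentNMF(BaseEstimator):
    """sklearn-style transformer around :func:`nmf_fit` / :func:`nmf_project`.

    ``fit(V)`` learns nonnegative loadings ``components_`` (d x features);
    ``transform(V)`` returns nonnegative latent scores (rows x d) for any
    matrix with matching columns, solving the W subproblem with the loadings
    frozen. ``fit_transform`` returns the training scores themselves.
    """

    def __init__(
        self,
        n_components: int = 4,
        max_iter: int = 500,
        tol: float = 1e-6,
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, V, y=None) -> "LatentNMF":
        result = nmf_fit(
            V,
            d=self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
            seed=self.random_state,
        )
        self.components_ = result.H
        self.embedding_ = result.W
        self.result_ = result
        self.reconstruction_err_ = result.reconstruction_error
        self.n_iter_ = result.n_iter
        return self

    def fit_transform(self, V, y=None) -> np.ndarray:
        return self.fit(V).embedding_

    def transform(self, V) -> np.ndarray:
        check_is_fitted(self, "components_")
        return nmf_project(
            self.components_,
            V,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
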