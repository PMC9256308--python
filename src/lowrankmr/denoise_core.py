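"""Weighted low-rank + sparse + Gaussian decomposition solver.

Model
-----
Given an observed matrix ``D`` the solver finds ``H`` (low-rank), ``S``
(sparse) and ``E`` (dense Gaussian residual) minimising

    sum_j w_Hj * sigma_j(H)  +  lambda1 * || W_s .* S ||_1  +  lambda2 * ||E||_F^2
    subject to  H + S + E = D

with reweighting rules ``w_Hj = c / (sigma_j(H) + eps)`` and
``w_s,ij = c / (|S_ij| + eps)`` — larger magnitudes are penalised less.

The unweighted baseline (``solve_rl``) sets every weight to one and pins
``E = 0``; it is ordinary robust PCA and has no mechanism to absorb dense
Gaussian noise.

Solver
------
The constrained problem is attacked with an inexact augmented-Lagrangian /
alternating-direction scheme: per sweep, ``H`` is updated by weighted
singular-value thresholding of ``D - S - E + Y/mu``, ``S`` by weighted
entrywise soft-thresholding of ``D - H - E + Y/mu``, ``E`` by the closed
form ``(mu / (mu + 2*lambda2)) * (D - H - S + Y/mu)``, then the multiplier
``Y <- Y + mu * (D - H - S - E)`` and ``mu <- rho * mu``.  Weights are
frozen from the previous iterate when applying each prox (one-step
reweighting), which keeps every subproblem closed-form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ImageMatrix",
    "WeightVector",
    "SolverConfig",
    "DecompositionResult",
    "weighted_svt",
    "weighted_soft_threshold",
    "update_noise_term",
    "update_weights",
    "solve_rlre",
    "solve_rl",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageMatrix:
    """A 2-D real-valued pixel array with a declared nominal intensity range."""

    values: np.ndarray
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite entries")
        lo, hi = self.intensity_range
        if not (math.isfinite(lo) and math.isfinite(hi)) or hi <= lo:
            raise ValueError(f"invalid intensity range {self.intensity_range!r}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "intensity_range", (float(lo), float(hi)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class WeightVector:
    """Non-negative per-singular-value weights plus the rule constants."""

    w: np.ndarray
    epsilon: float = 1e-2
    c: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64).ravel()
        if w.size == 0:
            raise ValueError("weight vector must be non-empty")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.c > 0:
            raise ValueError("c must be positive")
        object.__setattr__(self, "w", w)


@dataclass(frozen=True)
class SolverConfig:
    """Solver parameters.

    ``lambda1``, ``c_weight`` and ``mu0`` default to ``None`` meaning
    "resolve from the data": ``lambda1 = 1/sqrt(max(M, N))``,
    ``c_weight = sqrt(max(M, N))`` and ``mu0 = 1.25 / ||D||_2``.
    ``lambda2`` may be ``math.inf`` to disable the Gaussian term entirely.
    """

    lambda1: float | None = None
    lambda2: float = 0.5
    c_weight: float | None = None
    epsilon: float = 1e-2
    mu0: float | None = None
    rho: float = 1.5
    tol: float = 1e-7
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 is not None and not self.lambda1 > 0:
            raise ValueError("lambda1 must be positive")
        if not self.lambda2 > 0:
            raise ValueError("lambda2 must be positive")
        if self.c_weight is not None and not self.c_weight > 0:
            raise ValueError("c_weight must be positive")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive (division hazard)")
        if self.mu0 is not None and not self.mu0 > 0:
            raise ValueError("mu0 must be positive")
        if not self.rho > 1:
            raise ValueError("rho must exceed 1")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if not (isinstance(self.max_iter, int) and self.max_iter >= 1):
            raise ValueError("max_iter must be a positive integer")

    def resolve(self, shape: tuple[int, int], spectral_norm: float) -> "SolverConfig":
        """Fill data-dependent defaults for a matrix of the given shape."""
        big = float(max(shape))
        lam1 = self.lambda1 if self.lambda1 is not None else 1.0 / math.sqrt(big)
        c = self.c_weight if self.c_weight is not None else math.sqrt(big)
        mu0 = self.mu0
        if mu0 is None:
            mu0 = 1.25 / spectral_norm if spectral_norm > 0 else 1.25
        return SolverConfig(
            lambda1=lam1, lambda2=self.lambda2, c_weight=c, epsilon=self.epsilon,
            mu0=mu0, rho=self.rho, tol=self.tol, max_iter=self.max_iter,
            seed=self.seed,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "lambda1": self.lambda1,
            "lambda2": None if math.isinf(self.lambda2) else self.lambda2,
            "lambda2_infinite": math.isinf(self.lambda2),
            "c_weight": self.c_weight,
            "epsilon": self.epsilon,
            "mu0": self.mu0,
            "rho": self.rho,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SolverConfig":
        d = dict(d)
        if d.pop("lambda2_infinite", False):
            d["lambda2"] = math.inf
        if d.get("lambda2") is None:
            d.pop("lambda2", None)
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass(frozen=True)
class DecompositionResult:
    """The triple (H, S, E) plus convergence diagnostics."""

    H: np.ndarray
    S: np.ndarray
    E: np.ndarray
    iterations: int
    residual: float
    converged: bool
    objective_trace: tuple[float, ...] = field(default=(), repr=False)
    residual_trace: tuple[float, ...] = field(default=(), repr=False)

    def reconstruction(self) -> np.ndarray:
        return self.H + self.S + self.E


# ---------------------------------------------------------------------------
# Proximal building blocks
# ---------------------------------------------------------------------------


def _as_finite_matrix(Y: np.ndarray, name: str = "input") -> np.ndarray:
    arr = np.asarray(Y, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def _deterministic_svd(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full SVD with the sign of each left singular vector's largest-magnitude
    entry fixed positive, so repeated runs are bit-identical."""
    U, sig, Vt = np.linalg.svd(Y, full_matrices=False)
    lead = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[lead, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, sig, Vt * signs[:, None]


def weighted_svt(Y: np.ndarray, weights: WeightVector | np.ndarray, tau: float) -> np.ndarray:
    """Weighted singular-value thresholding.

    Solves ``argmin_X 0.5 * ||X - Y||_F^2 + tau * sum_j w_j * sigma_j(X)``
    for fixed weights: each singular value is shrunk by its own threshold,
    ``sigma_j -> max(sigma_j - tau * w_j, 0)``.

    The weights are sorted non-descending before being paired with the
    (non-ascending) singular values; this convention keeps the shrunk
    spectrum non-ascending, hence a valid set of singular values.
    """
    Y = _as_finite_matrix(Y, "Y")
    if not tau > 0:
        raise ValueError("tau must be positive")
    w = weights.w if isinstance(weights, WeightVector) else np.asarray(weights, dtype=np.float64).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    k = min(Y.shape)
    if w.size == 1:
        w = np.full(k, w[0])
    if w.size != k:
        raise ValueError(f"expected {k} weights, got {w.size}")
    U, sig, Vt = _deterministic_svd(Y)
    w = np.sort(w)  # non-descending weights against non-ascending sigma
    shrunk = np.maximum(sig - tau * w, 0.0)
    return (U * shrunk) @ Vt


def weighted_soft_threshold(Y: np.ndarray, weights: np.ndarray, tau: float) -> np.ndarray:
    """Entrywise prox of the weighted L1 norm:
    ``y -> sign(y) * max(|y| - tau * w, 0)``."""
    Y = _as_finite_matrix(Y, "Y")
    if not tau > 0:
        raise ValueError("tau must be positive")
    W = np.broadcast_to(np.asarray(weights, dtype=np.float64), Y.shape)
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    return np.sign(Y) * np.maximum(np.abs(Y) - tau * W, 0.0)


def update_noise_term(R: np.ndarray, lambda2: float, mu: float) -> np.ndarray:
    """Closed-form minimiser of ``lambda2*||E||_F^2 + (mu/2)*||E - R||_F^2``,
    namely ``E = (mu / (mu + 2*lambda2)) * R``.

    ``lambda2 = inf`` returns the zero matrix (the Gaussian term is disabled);
    ``lambda2 = 0`` returns ``R`` unchanged.
    """
    R = _as_finite_matrix(R, "R")
    if not mu > 0:
        raise ValueError("mu must be positive")
    if lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")
    if math.isinf(lambda2):
        return np.zeros_like(R)
    return (mu / (mu + 2.0 * lambda2)) * R


def update_weights(
    current: DecompositionResult, config: SolverConfig
) -> tuple[WeightVector, np.ndarray]:
    """Reweighting rules: ``w_Hj = c/(sigma_j(H) + eps)`` per singular value
    and ``w_s,ij = c/(|S_ij| + eps)`` per entry — inversely proportional to
    the current magnitudes, so strong structure is penalised less.
    """
    if not config.epsilon > 0:
        raise ValueError("epsilon must be positive (division hazard)")
    c = config.c_weight if config.c_weight is not None else math.sqrt(max(current.H.shape))
    sig = np.linalg.svd(current.H, compute_uv=False)
    w_h = WeightVector(c / (sig + config.epsilon), epsilon=config.epsilon, c=c)
    w_s = c / (np.abs(current.S) + config.epsilon)
    return w_h, w_s


# ---------------------------------------------------------------------------
# Main solvers
# ---------------------------------------------------------------------------


def _objective(
    H: np.ndarray, S: np.ndarray, E: np.ndarray,
    w_h: np.ndarray, w_s: np.ndarray, lambda1: float, lambda2: float,
) -> float:
    sig = np.linalg.svd(H, compute_uv=False)
    obj = float(np.sort(w_h) @ np.sort(sig)[::-1])  # weight convention as applied
    obj += lambda1 * float(np.sum(w_s * np.abs(S)))
    if not math.isinf(lambda2):
        obj += lambda2 * float(np.sum(E * E))
    return obj


def _solve(
    D: ImageMatrix | np.ndarray,
    config: SolverConfig,
    *,
    weighted: bool,
    noise_term: bool,
) -> DecompositionResult:
    values = D.values if isinstance(D, ImageMatrix) else _as_finite_matrix(D, "D")
    m, n = values.shape
    norm_d = float(np.linalg.norm(values))
    spectral = float(np.linalg.norm(values, 2)) if norm_d > 0 else 0.0
    cfg = config.resolve((m, n), spectral)
    lam1, lam2, c, eps = cfg.lambda1, cfg.lambda2, cfg.c_weight, cfg.epsilon
    if not noise_term:
        lam2 = math.inf

    H = values.copy()
    S = np.zeros_like(values)
    E = np.zeros_like(values)
    Y = np.zeros_like(values)
    mu = cfg.mu0
    denom = norm_d if norm_d > 0 else 1.0

    unit_w = np.ones(min(m, n))
    obj_trace: list[float] = []
    res_trace: list[float] = []
    # H = D is feasible by construction, so convergence is only assessed
    # after a sweep has actually applied the proximal updates
    residual = math.inf
    converged = False
    it = 0
    while not converged and it < cfg.max_iter:
        it += 1
        if weighted and it > 1:
            # one-step reweighting: weights frozen from the previous iterate.
            # The first sweep runs unweighted — reweighting needs a previous
            # solution, and H = D at initialisation would otherwise hand every
            # direction already present in D a protective low weight.
            sig = np.linalg.svd(H, compute_uv=False)
            w_h = c / (sig + eps)
            w_s = c / (np.abs(S) + eps)
        else:
            w_h = unit_w
            w_s = 1.0
        H = weighted_svt(values - S - E + Y / mu, w_h, 1.0 / mu)
        S = weighted_soft_threshold(values - H - E + Y / mu, w_s, lam1 / mu)
        if noise_term:
            E = update_noise_term(values - H - S + Y / mu, lam2, mu)
        R = values - H - S - E
        Y = Y + mu * R
        mu *= cfg.rho
        residual = float(np.linalg.norm(R)) / denom
        res_trace.append(residual)
        w_s_arr = w_s if weighted else np.ones_like(S)
        obj_trace.append(_objective(H, S, E, np.atleast_1d(w_h), w_s_arr, lam1, lam2))
        if residual <= cfg.tol:
            converged = True

    if not converged:
        logger.warning(
            "decomposition did not converge in %d iterations (residual %.3e > tol %.3e)",
            it, residual, cfg.tol,
        )
    return DecompositionResult(
        H=H, S=S, E=E, iterations=it, residual=residual, converged=converged,
        objective_trace=tuple(obj_trace), residual_trace=tuple(res_trace),
    )


def solve_rlre(
    D: ImageMatrix | np.ndarray, config: SolverConfig | None = None, *, weighted: bool = True
) -> DecompositionResult:
    """Full weighted three-term decomposition ``D = H + S + E``.

    ``weighted=False`` disables the reweighting rules (all weights one),
    which together with ``lambda2 = math.inf`` reproduces the unweighted
    baseline :func:`solve_rl` sweep-for-sweep.
    """
    return _solve(D, config or SolverConfig(), weighted=weighted, noise_term=True)


def solve_rl(D: ImageMatrix | np.ndarray, config: SolverConfig | None = None) -> DecompositionResult:
    """Unweighted low-rank + sparse baseline: unit weights, ``E`` pinned to 0."""
    return _solve(D, config or SolverConfig(), weighted=False, noise_term=False)
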