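"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's closed-form prox implementations:
each solves the scalar (or per-singular-value) minimisation by dense grid
search with local refinement.
"""

import numpy as np


def scalar_prox_bruteforce(y: float, w: float, tau: float, span: float = None,
                           rounds: int = 6, grid: int = 2001) -> float:
    """argmin_x 0.5*(x - y)^2 + tau*w*|x| by grid search + refinement."""
    span = span if span is not None else max(abs(y), 1.0) * 1.5
    lo, hi = -span, span
    best = 0.0
    for _ in range(rounds):
        xs = np.linspace(lo, hi, grid)
        obj = 0.5 * (xs - y) ** 2 + tau * w * np.abs(xs)
        best = xs[np.argmin(obj)]
        half = (hi - lo) / grid * 2
        lo, hi = best - half, best + half
    return float(best)


def singular_value_prox_bruteforce(sig: float, w: float, tau: float) -> float:
    """argmin_{x >= 0} 0.5*(x - sig)^2 + tau*w*x by grid search + refinement."""
    lo, hi = 0.0, max(sig, 1.0) * 1.5
    best = 0.0
    for _ in range(6):
        xs = np.linspace(lo, hi, 2001)
        obj = 0.5 * (xs - sig) ** 2 + tau * w * xs
        best = xs[np.argmin(obj)]
        half = (hi - lo) / 2001 * 2
        lo, hi = max(best - half, 0.0), best + half
    return float(best)


def svt_objective(X: np.ndarray, Y: np.ndarray, w_sorted_desc_pairing: np.ndarray,
                  tau: float) -> float:
    """0.5*||X - Y||_F^2 + tau * sum_j w_j * sigma_j(X), weights paired with
    the non-ascending singular values after sorting non-descending."""
    sig = np.linalg.svd(X, compute_uv=False)
    w = np.sort(np.asarray(w_sorted_desc_pairing, dtype=float))
    return 0.5 * float(np.sum((X - Y) ** 2)) + tau * float(w @ sig)


def l1_objective(X: np.ndarray, Y: np.ndarray, W: np.ndarray, tau: float) -> float:
    return 0.5 * float(np.sum((X - Y) ** 2)) + tau * float(np.sum(W * np.abs(X)))


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Textbook formula N*(ad - bc)^2 / (r1*r2*c1*c2), df = 1."""
    from scipy.stats import chi2 as chi2_dist

    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = num / den
    return float(stat), float(chi2_dist.sf(stat, df=1))
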