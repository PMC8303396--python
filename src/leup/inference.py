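"""Fitting the LEUP sensitivity beta to observed cone proportions.

The single free parameter beta is estimated by minimizing the Kullback-Leibler
divergence D(P_exp || Q(beta)) between the experimentally observed cone
occurrence proportions P and the model weights
Q_i(beta) = sigma_i^(-beta) / sum_j sigma_j^(-beta), where sigma_i is the
per-type NND standard deviation.  The divergence direction is fixed:
experimental proportions play the role of P, the model the role of Q.

The fit is a coarse grid scan followed by bounded scalar refinement; the whole
curve DKL(beta) is retained for reporting and for threshold intervals of
plausible beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import ConeMosaicStats, gaussian_leup_weights

__all__ = ["BetaFitResult", "kl_divergence", "dkl_of_beta", "fit_beta", "beta_plausible_interval"]


@dataclass(frozen=True)
class BetaFitResult:
    """Outcome of the KL fit: argmin, minimum divergence and the scanned curve."""

    beta_hat: float
    dkl_min: float
    dkl_curve: np.ndarray  # shape (n, 2): columns beta, DKL(beta)
    search_bounds: tuple[float, float]


def kl_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Kullback-Leibler divergence sum_i p_i ln(p_i/q_i) in nats.

    Terms with p_i = 0 contribute zero; p_i > 0 with q_i = 0 is an error
    (infinite divergence).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    support = p > 0
    if np.any(q[support] <= 0):
        raise ValueError("infinite divergence: p_i > 0 where q_i = 0")
    ps, qs = p[support], q[support]
    return float((ps * (np.log(ps) - np.log(qs))).sum())


def dkl_of_beta(stats: ConeMosaicStats, beta: float | np.ndarray) -> float | np.ndarray:
    """DKL(P_exp || Q(beta)) as a function of beta; vectorized over beta."""
    p = stats.proportions
    log_sd = np.log(stats.nnd_sd)
    betas = np.atleast_1d(np.asarray(beta, dtype=float))
    # log Q_i(beta) = -beta log sigma_i - logsumexp_j(-beta log sigma_j)
    expo = -betas[:, None] * log_sd[None, :]
    expo -= expo.max(axis=1, keepdims=True)
    log_q = expo - np.log(np.exp(expo).sum(axis=1, keepdims=True))
    support = p > 0
    dkl = (p[support] * (np.log(p[support])[None, :] - log_q[:, support])).sum(axis=1)
    return float(dkl[0]) if np.isscalar(beta) or np.ndim(beta) == 0 else dkl


def fit_beta(
    stats: ConeMosaicStats,
    bounds: tuple[float, float] = (0.0, 10.0),
    grid_step: float = 1e-3,
    tol: float = 1e-8,
) -> BetaFitResult:
    """Minimize DKL(P_exp || Q(beta)) over beta.

    A grid scan at ``grid_step`` over ``bounds`` locates the basin; bounded
    Brent refinement around the grid argmin polishes it to ``tol``.
    """
    low, high = float(bounds[0]), float(bounds[1])
    if not low < high:
        raise ValueError("bounds must satisfy low < high")
    grid = np.arange(low, high + grid_step / 2, grid_step)
    dkl_grid = dkl_of_beta(stats, grid)
    if not np.all(np.isfinite(dkl_grid)):
        raise ValueError("non-finite DKL on the search grid")
    k = int(np.argmin(dkl_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    if lo == hi:  # single-point grid
        beta_hat, dkl_min = float(grid[k]), float(dkl_grid[k])
    else:
        res = minimize_scalar(
            lambda b: dkl_of_beta(stats, float(b)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        beta_hat, dkl_min = float(res.x), float(res.fun)
        if dkl_grid[k] < dkl_min:  # refinement should never be worse
            beta_hat, dkl_min = float(grid[k]), float(dkl_grid[k])
    curve = np.column_stack([grid, dkl_grid])
    return BetaFitResult(beta_hat=beta_hat, dkl_min=dkl_min, dkl_curve=curve, search_bounds=(low, high))


def beta_plausible_interval(
    stats: ConeMosaicStats,
    dkl_threshold: float,
    bounds: tuple[float, float] = (0.0, 10.0),
    fit: BetaFitResult | None = None,
) -> tuple[float, float]:
    """Connected interval of beta around the optimum where DKL <= threshold.

    Endpoints are located by bisection (brentq) to 1e-6.  If the curve stays
    below the threshold all the way to a search bound, that bound is returned
    as the endpoint.
    """
    if fit is None:
        fit = fit_beta(stats, bounds=bounds)
    if dkl_threshold < fit.dkl_min:
        raise ValueError("threshold below the minimum divergence")
    if dkl_threshold == fit.dkl_min:
        return (fit.beta_hat, fit.beta_hat)

    def g(b: float) -> float:
        return float(dkl_of_beta(stats, b)) - dkl_threshold

    low, high = fit.search_bounds
    left = low if g(low) <= 0 else brentq(g, low, fit.beta_hat, xtol=1e-6)
    right = high if g(high) <= 0 else brentq(g, fit.beta_hat, high, xtol=1e-6)
    return (float(left), float(right))
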