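"""Receptor-ligand sensing models grounding beta = 2 as optimal sensing.

A membrane receptor of concentration x binds one or two independent ligand
species; complex concentration c relaxes as dc/dt = k1 x y1 + k2 x y2 - d c,
so for fast decay the steady state is a linear combination of the ligand
signals.  Reading the combination coefficients as LEUP weights
sigma_i^(-beta) gives a fused microenvironment estimate whose noise variance
is minimized exactly at beta = 2 — the minimum-variance estimator.  For a
single diffusing (Poisson) ligand, receptor occupancy is inversely
proportional to the ligand variance, which is the same beta = 2 weighting in
unnormalized form (the perfect-monitoring limit of physical sensing bounds).

Ligand consumption feeding back on x is omitted throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from .core import gaussian_leup_weights

__all__ = [
    "BindingParams",
    "complex_steady_state",
    "relax_to_steady_state",
    "fused_estimate",
    "fused_variance",
    "berg_purcell_check",
]


@dataclass(frozen=True)
class BindingParams:
    """Rate constants and concentrations of the binding system.

    Two-ligand systems use (k1, y1) and (k2, y2); single-ligand systems use
    (k_plus, y).  ``d`` is the complex decay rate (per time) and must be
    positive; concentrations are nonnegative.
    """

    d: float
    x: float
    k1: float = 0.0
    k2: float = 0.0
    y1: float = 0.0
    y2: float = 0.0
    k_plus: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("decay rate d must be positive")
        if min(self.x, self.y1, self.y2, self.y) < 0:
            raise ValueError("concentrations must be nonnegative")


def complex_steady_state(params: BindingParams) -> float:
    """Closed-form steady state (k1 x y1 + k2 x y2 + k+ x y) / d."""
    return (
        params.k1 * params.x * params.y1
        + params.k2 * params.x * params.y2
        + params.k_plus * params.x * params.y
    ) / params.d


def relax_to_steady_state(params: BindingParams, c0: float = 0.0, t_end: float | None = None) -> float:
    """Integrate dc/dt = (production) - d c and return c(t_end).

    Defaults to t_end = 20/d, by which the linear relaxation
    c(t) = c_eq + (c0 - c_eq) e^(-d t) has converged to c_eq within ~2e-9
    relative.
    """
    if t_end is None:
        t_end = 20.0 / params.d
    production = (
        params.k1 * params.x * params.y1
        + params.k2 * params.x * params.y2
        + params.k_plus * params.x * params.y
    )
    sol = solve_ivp(
        lambda _t, c: production - params.d * c,
        (0.0, t_end),
        [float(c0)],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return float(sol.y[0, -1])


def fused_estimate(sigmas: Sequence[float], beta: float, ligands: Sequence[float]) -> float:
    """LEUP-weighted fusion sum_i w_i y_i with w = sigma^(-beta) weights."""
    y = np.asarray(ligands, dtype=float)
    w = gaussian_leup_weights(sigmas, beta)
    if w.size != y.size:
        raise ValueError("sigmas and ligands must have the same length")
    return float(w @ y)


def fused_variance(sigmas: Sequence[float], beta: float) -> float:
    """Noise variance sum_i w_i^2 sigma_i^2 of the fused estimate.

    For independent signals y_i with SDs sigma_i; minimized over beta at
    beta = 2 (the minimum-variance weights).
    """
    sd = np.asarray(sigmas, dtype=float)
    w = gaussian_leup_weights(sd, beta)
    return float((w**2 * sd**2).sum())


def berg_purcell_check(
    x_grid: Sequence[float],
    k_plus: float = 1.0,
    d: float = 1.0,
    jitter_cv: float = 0.0,
    seed: int | None = None,
) -> float:
    """Slope of ln P(x) against ln sigma_Y for a Poisson ligand; -2 exactly.

    Receptor occupancy P(x) = (k+/d) x together with P proportional to 1/y
    fixes y(x) = d/(k+ x); a Poisson ligand count has variance sigma_Y^2 = y,
    so the regression slope of ln P on ln sigma_Y is the power-law exponent
    relating occupancy to ligand noise.  Optional multiplicative lognormal-like
    jitter (coefficient of variation ``jitter_cv``, seeded) perturbs y before
    the regression.
    """
    x = np.asarray(x_grid, dtype=float)
    if x.size < 2 or np.any(x <= 0) or np.unique(x).size < 2:
        raise ValueError("x_grid must contain at least two distinct positive values")
    p = (k_plus / d) * x
    y = 1.0 / p
    if jitter_cv > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + jitter_cv * rng.standard_normal(y.size))
        if np.any(y <= 0):
            raise ValueError("jitter produced non-positive ligand concentrations")
    sigma_y = np.sqrt(y)
    return float(linregress(np.log(sigma_y), np.log(p)).slope)
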