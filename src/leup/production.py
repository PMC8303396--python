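"""Total entropy production as a function of the cell sensing radius.

With a Gaussian sensed microenvironment whose variance scales with the sensing
radius R as sigma_d^2 = V R^A for the differentiated (hyperuniform, A < D)
mosaic and sigma_s^2 = U R^D for the Poisson progenitor pattern, the total
entropy production of the differentiation transition becomes

    f(R) = C0 + C1 (beta_d - beta_s) + (1/2) ln(V^beta_d / U^beta_s)
           + Gamma ln R + dmu R^D,

with C1 = (1/2) ln(2 pi e), Gamma = (A beta_d - D beta_s) / 2, and dmu the
net density-weighted asymmetric-division intensity difference.  C0 lumps the
heat term, the information gain and the partition-function ratio into one
constant.

The stationary point R_c = (-Gamma / (dmu D))^(1/D) exists whenever
Gamma/dmu < 0; its character follows the sign of Gamma (minimum for Gamma < 0,
maximum for Gamma > 0, from the second derivative -Gamma D / R_c^2).
Robust differentiation requires f > 0, so the sign structure of f over R and
over the (beta_s, beta_d) plane delimits the admissible sensing radii.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "C1",
    "EntropyProductionParams",
    "CriticalRadiusResult",
    "gamma_coefficient",
    "entropy_production_f",
    "delta_s_leup",
    "critical_radius",
    "radius_scan",
    "feasible_region_scan",
]

#: C1 = (1/2) ln(2 pi e), the Gaussian entropy constant.
C1 = 0.5 * math.log(2.0 * math.pi * math.e)


@dataclass(frozen=True)
class EntropyProductionParams:
    """Parameters of the radius-dependent entropy production f(R).

    ``c0``: lumped constant (heat - information gain - ln Z1/Z2), nats.
    ``beta_s``/``beta_d``: LEUP sensitivities of progenitor and differentiated
    cells.  ``u``/``v`` (> 0): neighbour densities of progenitor and cone
    patterns.  ``a``: hyperuniformity exponent of the differentiated mosaic
    (A < D for hyperuniform patterns).  ``d``: spatial dimension, 2 or 3.
    ``delta_mu``: net division-intensity x density difference (per R^D).
    """

    c0: float
    beta_s: float
    beta_d: float
    u: float = 1.0
    v: float = 1.0
    a: float = 1.0
    d: int = 2
    delta_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.u <= 0 or self.v <= 0:
            raise ValueError("densities U, V must be positive")
        if self.d not in (2, 3):
            raise ValueError("spatial dimension must be 2 or 3")


@dataclass(frozen=True)
class CriticalRadiusResult:
    """Stationary radius of f(R), its character, and f there.

    ``kind`` is "minimum" (Gamma < 0), "maximum" (Gamma > 0) or "none" when no
    interior extremum exists (Gamma/dmu >= 0, or a degenerate parameter set);
    in the latter case ``r_c`` and ``f_at_rc`` are None.
    """

    r_c: float | None
    kind: Literal["minimum", "maximum", "none"]
    f_at_rc: float | None


def gamma_coefficient(params: EntropyProductionParams) -> float:
    """Gamma = (A beta_d - D beta_s) / 2, the ln R coefficient of f."""
    return 0.5 * (params.a * params.beta_d - params.d * params.beta_s)


def delta_s_leup(params: EntropyProductionParams, r: float | np.ndarray) -> float | np.ndarray:
    """Sensing-entropy change <dS_LEUP> at radius R (nats).

    (beta_d - beta_s) C1 + (1/2) ln(V^beta_d / U^beta_s) + Gamma ln R; the
    radius-dependent part of f, so f = C0 + delta_s_leup + dmu R^D identically.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("sensing radius must be positive")
    const = (params.beta_d - params.beta_s) * C1 + 0.5 * (
        params.beta_d * math.log(params.v) - params.beta_s * math.log(params.u)
    )
    out = const + gamma_coefficient(params) * np.log(r)
    return float(out) if out.ndim == 0 else out


def entropy_production_f(params: EntropyProductionParams, r: float | np.ndarray) -> float | np.ndarray:
    """Total entropy production f(R), nats; vectorized over R > 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("sensing radius must be positive")
    out = params.c0 + delta_s_leup(params, r) + params.delta_mu * r**params.d
    return float(out) if np.ndim(out) == 0 else out


def critical_radius(params: EntropyProductionParams) -> CriticalRadiusResult:
    """Closed-form stationary radius R_c = (-Gamma/(dmu D))^(1/D), if any.

    Returns kind "none" when dmu = 0 (f is Gamma ln R + const, monotone) or
    when Gamma/dmu >= 0 (no positive stationary point).
    """
    gamma = gamma_coefficient(params)
    if params.delta_mu == 0 or gamma == 0 or gamma / params.delta_mu >= 0:
        return CriticalRadiusResult(r_c=None, kind="none", f_at_rc=None)
    r_c = (-gamma / (params.delta_mu * params.d)) ** (1.0 / params.d)
    kind = "minimum" if gamma < 0 else "maximum"
    return CriticalRadiusResult(r_c=float(r_c), kind=kind, f_at_rc=float(entropy_production_f(params, r_c)))


def radius_scan(params: EntropyProductionParams, radii: Sequence[float]) -> pd.DataFrame:
    """Evaluate f over a radius grid; columns R, f, f_positive."""
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("empty radius grid")
    f = entropy_production_f(params, radii)
    return pd.DataFrame({"R": radii, "f": f, "f_positive": f > 0})


def feasible_region_scan(
    base: EntropyProductionParams,
    beta_s: Sequence[float],
    beta_d: Sequence[float],
    delta_mu: Sequence[float] | None = None,
    radius: float | Literal["critical"] = "critical",
) -> pd.DataFrame:
    """Classify the (beta_s, beta_d[, dmu]) grid by the sign of f and Gamma.

    At each grid point f is evaluated at the fixed ``radius`` or at the
    critical radius when ``radius="critical"`` (NaN where none exists).  The
    ternary ``region`` column distinguishes robust points (f > 0 with
    Gamma < 0, i.e. a true entropy-production minimum), positive points
    without that structure, and non-positive points.
    """
    bs = np.atleast_1d(np.asarray(beta_s, dtype=float))
    bd = np.atleast_1d(np.asarray(beta_d, dtype=float))
    dmu: Iterable[float] = (
        [base.delta_mu] if delta_mu is None else np.atleast_1d(np.asarray(delta_mu, dtype=float))
    )
    if bs.size == 0 or bd.size == 0:
        raise ValueError("empty grid")
    rows = []
    for s, d_, m in itertools.product(bs, bd, dmu):
        p = replace(base, beta_s=float(s), beta_d=float(d_), delta_mu=float(m))
        gamma = gamma_coefficient(p)
        if radius == "critical":
            crit = critical_radius(p)
            f_val = math.nan if crit.f_at_rc is None else crit.f_at_rc
            r_used = math.nan if crit.r_c is None else crit.r_c
        else:
            r_used = float(radius)
            f_val = float(entropy_production_f(p, r_used))
        positive = bool(f_val > 0) if math.isfinite(f_val) else False
        if positive and gamma < 0:
            region = "robust"
        elif positive:
            region = "positive_no_minimum"
        else:
            region = "nonpositive"
        rows.append(
            {
                "beta_s": float(s),
                "beta_d": float(d_),
                "delta_mu": float(m),
                "R": r_used,
                "f": f_val,
                "gamma": gamma,
                "f_positive": positive,
                "gamma_negative": gamma < 0,
                "region": region,
            }
        )
    return pd.DataFrame(rows)
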