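"""From NND variance to sensing radius and hyperuniformity exponent.

The count/NND variance of a cone mosaic relates to the sensing radius R through
the empirical three-coefficient model

    sigma^2(R) = M1 R^2 + M2 R ln R + M3 R,

whose coefficients are an external, per-cone-type input (they are a published
fit to mosaic data and are never bundled here as authoritative values).
Inverting the model at the observed per-type NND standard deviation gives an
average sensing radius per cone type.  Approximating the variance as a pure
power law sigma_d^2 = V R^A with V = 1 then yields the hyperuniformity
exponent A = 2 ln(sigma) / ln(R); hyperuniform mosaics satisfy A < D (= 2 for
the planar retina).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import ConeMosaicStats

__all__ = [
    "VarianceModelCoeffs",
    "SensingRadiusTable",
    "variance_model",
    "solve_sensing_radius",
    "hyperuniformity_exponent",
    "radii_table",
    "exponent_table",
    "load_coeffs_config",
    "KRAM_MEAN_SENSING_RADII",
]

#: Published mean sensing radii (micrometres) of the five chicken cone types,
#: used as direct inputs when the variance-model coefficients are unavailable.
KRAM_MEAN_SENSING_RADII: dict[str, float] = {
    "double": 0.786,
    "green": 1.426,
    "red": 2.006,
    "blue": 2.288,
    "violet": 3.553,
}


@dataclass(frozen=True)
class VarianceModelCoeffs:
    """Coefficients (M1, M2, M3) of sigma^2(R) = M1 R^2 + M2 R ln R + M3 R."""

    m1: float
    m2: float
    m3: float


@dataclass(frozen=True)
class SensingRadiusTable:
    """Per-cone-type sensing radii (micrometres) and exponents A."""

    labels: tuple[str, ...]
    radii: np.ndarray
    exponents_a: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"label": self.labels, "sensing_radius": self.radii, "exponent_A": self.exponents_a}
        ).to_csv(path, index=False)


def variance_model(coeffs: VarianceModelCoeffs, r: float | np.ndarray) -> float | np.ndarray:
    """Forward model sigma^2(R); R must be positive (R ln R is undefined at 0)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    out = coeffs.m1 * r**2 + coeffs.m2 * r * np.log(r) + coeffs.m3 * r
    return float(out) if out.ndim == 0 else out


def solve_sensing_radius(
    coeffs: VarianceModelCoeffs,
    sigma: float,
    bracket: tuple[float, float] = (1e-6, 1e2),
) -> float:
    """Invert sigma^2(R) = sigma^2 for R by bracketed root finding.

    The bracket is scanned on a log-spaced grid for sign changes of
    sigma^2(R) - sigma^2; the root in the first sign-change subinterval is
    returned (the smallest root in the bracket), with a warning if the model
    crosses the target more than once.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    target = sigma**2

    def g(r: float) -> float:
        return float(variance_model(coeffs, r)) - target

    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < low < high")
    grid = np.geomspace(lo, hi, 512)
    vals = np.array([g(r) for r in grid])
    signs = np.sign(vals)
    crossings = np.nonzero(np.diff(signs) != 0)[0]
    exact = np.nonzero(vals == 0)[0]
    if exact.size:
        roots = [float(grid[exact[0]])]
    elif crossings.size == 0:
        raise ValueError("no sign change of sigma^2(R) - target in the bracket")
    else:
        roots = []
        for k in crossings:
            roots.append(float(brentq(g, grid[k], grid[k + 1], xtol=1e-14, rtol=1e-12)))
    if len(roots) > 1:
        warnings.warn(
            f"multiple radii solve sigma^2(R)={target:.6g}; returning the smallest ({roots[0]:.6g})",
            stacklevel=2,
        )
    return roots[0]


def hyperuniformity_exponent(sigma: float, radius: float) -> float:
    """A = 2 ln(sigma) / ln(R), the power-law exponent with V fixed to 1.

    Undefined at R = 1 (ln R = 0); sigma and R must be positive.
    """
    if sigma <= 0 or radius <= 0:
        raise ValueError("sigma and radius must be positive")
    if radius == 1.0:
        raise ValueError("exponent undefined at radius 1 (ln R = 0)")
    return 2.0 * math.log(sigma) / math.log(radius)


def radii_table(
    stats: ConeMosaicStats,
    coeffs_by_label: Mapping[str, VarianceModelCoeffs | Sequence[float]],
    bracket: tuple[float, float] = (1e-6, 1e2),
    dimension: int = 2,
) -> SensingRadiusTable:
    """Solve the sensing radius and exponent A per cone type.

    ``coeffs_by_label`` maps every label in ``stats`` to (M1, M2, M3).  Types
    whose exponent violates the hyperuniformity assumption A < dimension are
    reported with a warning, not an error.
    """
    missing = [lab for lab in stats.labels if lab not in coeffs_by_label]
    if missing:
        raise KeyError(f"missing variance-model coefficients for labels: {missing}")
    radii, exponents = [], []
    for lab, sd in zip(stats.labels, stats.nnd_sd):
        c = coeffs_by_label[lab]
        if not isinstance(c, VarianceModelCoeffs):
            c = VarianceModelCoeffs(*c)
        r = solve_sensing_radius(c, float(sd), bracket=bracket)
        radii.append(r)
        exponents.append(hyperuniformity_exponent(float(sd), r))
    radii = np.asarray(radii)
    exponents = np.asarray(exponents)
    bad = [lab for lab, a in zip(stats.labels, exponents) if a >= dimension]
    if bad:
        warnings.warn(f"exponent A >= {dimension} (not hyperuniform) for: {bad}", stacklevel=2)
    return SensingRadiusTable(labels=stats.labels, radii=radii, exponents_a=exponents)


def exponent_table(stats: ConeMosaicStats, radii_by_label: Mapping[str, float]) -> SensingRadiusTable:
    """Exponents A from directly supplied mean radii (skipping the solve step)."""
    missing = [lab for lab in stats.labels if lab not in radii_by_label]
    if missing:
        raise KeyError(f"missing radii for labels: {missing}")
    radii = np.array([float(radii_by_label[lab]) for lab in stats.labels])
    exps = np.array(
        [hyperuniformity_exponent(float(sd), r) for sd, r in zip(stats.nnd_sd, radii)]
    )
    return SensingRadiusTable(labels=stats.labels, radii=radii, exponents_a=exps)


def load_coeffs_config(path: str | Path) -> dict[str, VarianceModelCoeffs]:
    """Read a JSON mapping label -> [M1, M2, M3]."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {str(lab): VarianceModelCoeffs(*map(float, vals)) for lab, vals in raw.items()}
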