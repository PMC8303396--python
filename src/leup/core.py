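"""Steady-state phenotype distributions under the least microenvironmental
uncertainty principle (LEUP).

A cell choosing among a finite set of fates x_i is modelled as a maximum-entropy
decision-maker whose fate distribution is tilted against the entropy of the
microenvironment it senses,

    P(x_i) = exp(-beta * S_i - mu * N_i) / Z(beta, mu),

where ``S_i = S(y | x_i)`` is the Shannon entropy (nats) of the microenvironment
conditioned on fate i, ``N_i`` is the expected number of neighbours entering the
asymmetric-division term, ``beta`` is the sensing sensitivity and ``mu`` the
asymmetric-division intensity.  When the sensed microenvironment is Gaussian
with per-fate nearest-neighbour-distance spread sigma_i and mu = 0 the
distribution collapses to the power-law weights

    P(x_i) = sigma_i^(-beta) / sum_j sigma_j^(-beta),

which at beta = 2 is the minimum-variance estimator of sensor fusion.

All entropies are in nats and the Boltzmann constant is taken to be 1
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ConeMosaicStats",
    "LEUPModel",
    "LEUPDistribution",
    "leup_distribution",
    "gaussian_leup_weights",
    "gaussian_microenv_entropy",
    "internal_entropy",
    "internal_energy",
    "min_variance_weights",
    "load_fixture",
    "FIXTURES",
]

_DATA_DIR = Path(__file__).parent / "data"

#: Named packaged cone-statistics tables.  ``kram2010_chicken`` carries the
#: published chicken cone occurrence proportions and per-type NND standard
#: deviations (micrometres) for the five avian cone types.
FIXTURES = {"kram2010_chicken": _DATA_DIR / "kram2010_chicken.csv"}

_PROP_SUM_ATOL = 1e-9


@dataclass(frozen=True)
class ConeMosaicStats:
    """Per-type summary statistics of a cone photoreceptor mosaic.

    Parameters
    ----------
    labels
        Ordered cone-type names (e.g. green, red, blue, violet, double).
    proportions
        Occurrence proportion of each type; nonnegative, summing to 1.
    nnd_sd
        Standard deviation of the nearest-neighbour-distance (NND)
        distribution of each type, in micrometres; strictly positive.
    nnd_mean
        Optional per-type NND mean, in micrometres.
    """

    labels: tuple[str, ...]
    proportions: np.ndarray
    nnd_sd: np.ndarray
    nnd_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        props = np.asarray(self.proportions, dtype=float)
        sd = np.asarray(self.nnd_sd, dtype=float)
        if not (len(labels) == props.size == sd.size):
            raise ValueError("labels, proportions and nnd_sd must have equal length")
        if props.size == 0:
            raise ValueError("empty statistics table")
        if np.any(props < 0):
            raise ValueError("proportions must be nonnegative")
        total = props.sum()
        if abs(total - 1.0) > _PROP_SUM_ATOL:
            # tolerate rounded published tables, reject anything else
            if 0.99 <= total <= 1.01:
                props = props / total
            else:
                raise ValueError(f"proportions sum to {total:.6f}, not 1")
        if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
            raise ValueError("nnd_sd must be strictly positive and finite")
        mean = self.nnd_mean
        if mean is not None:
            mean = np.asarray(mean, dtype=float)
            if mean.size != props.size:
                raise ValueError("nnd_mean length mismatch")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "nnd_sd", sd)
        object.__setattr__(self, "nnd_mean", mean)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConeMosaicStats":
        """Read a ``label,proportion,nnd_mean,nnd_sd`` CSV table."""
        df = pd.read_csv(path)
        required = {"label", "proportion", "nnd_sd"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        mean = None
        if "nnd_mean" in df.columns and df["nnd_mean"].notna().all():
            mean = df["nnd_mean"].to_numpy(float)
        return cls(
            labels=tuple(df["label"].astype(str)),
            proportions=df["proportion"].to_numpy(float),
            nnd_sd=df["nnd_sd"].to_numpy(float),
            nnd_mean=mean,
        )

    def to_csv(self, path: str | Path) -> None:
        mean = self.nnd_mean if self.nnd_mean is not None else [np.nan] * len(self)
        pd.DataFrame(
            {
                "label": self.labels,
                "proportion": self.proportions,
                "nnd_mean": mean,
                "nnd_sd": self.nnd_sd,
            }
        ).to_csv(path, index=False)


def load_fixture(name: str) -> ConeMosaicStats:
    """Load a packaged cone-statistics table by name (see ``FIXTURES``)."""
    try:
        path = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return ConeMosaicStats.from_csv(path)


@dataclass(frozen=True)
class LEUPModel:
    """Parameters of the discrete LEUP steady state.

    ``microenv_entropy[i]`` is S(y|x_i) in nats and ``neighbor_count[i]`` the
    expected neighbour count N(y|x_i); ``beta`` is the sensing sensitivity and
    ``mu`` (>= 0) the asymmetric-division intensity.
    """

    beta: float
    mu: float
    microenv_entropy: np.ndarray
    neighbor_count: np.ndarray

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.microenv_entropy, dtype=float))
        n = np.atleast_1d(np.asarray(self.neighbor_count, dtype=float))
        if s.size == 0:
            raise ValueError("empty state set")
        if s.shape != n.shape:
            raise ValueError("microenv_entropy and neighbor_count must match in length")
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(n)):
            raise ValueError("non-finite entropies or neighbour counts")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if np.any(n < 0):
            raise ValueError("neighbour counts must be nonnegative")
        object.__setattr__(self, "microenv_entropy", s)
        object.__setattr__(self, "neighbor_count", n)


@dataclass(frozen=True)
class LEUPDistribution:
    """Normalized fate probabilities with the log partition function ln Z."""

    probs: np.ndarray
    log_partition: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be a probability vector (sum 1 within 1e-12)")
        object.__setattr__(self, "probs", p)


def leup_distribution(model: LEUPModel) -> LEUPDistribution:
    """Evaluate P(x_i) ∝ exp(-beta*S_i - mu*N_i) on the discrete state set.

    Uses a log-sum-exp shift so that large ``|beta|`` (scans reach +-50) do not
    overflow.  Returns the probabilities and ln Z.
    """
    exponent = -model.beta * model.microenv_entropy - model.mu * model.neighbor_count
    log_z = float(logsumexp(exponent))
    probs = np.exp(exponent - log_z)
    probs /= probs.sum()  # remove residual rounding
    return LEUPDistribution(probs=probs, log_partition=log_z)


def gaussian_leup_weights(nnd_sd: Sequence[float], beta: float) -> np.ndarray:
    """Power-law fate weights sigma_i^(-beta) / sum_j sigma_j^(-beta).

    This is the LEUP steady state for a Gaussian microenvironment with mu = 0,
    i.e. ``leup_distribution`` with S_i = (1/2) ln(2*pi*e*sigma_i^2).
    """
    sd = np.asarray(nnd_sd, dtype=float)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("all sigma must be strictly positive and finite")
    log_w = -beta * np.log(sd)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


def gaussian_microenv_entropy(nnd_sd: Sequence[float]) -> np.ndarray:
    """Differential entropy (1/2) ln(2*pi*e*sigma^2) of a Gaussian, in nats."""
    sd = np.asarray(nnd_sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sigma must be positive")
    return 0.5 * np.log(2.0 * np.pi * np.e * sd**2)


def min_variance_weights(nnd_sd: Sequence[float]) -> np.ndarray:
    """Minimum-variance fusion weights sigma_i^(-2)/sum_j sigma_j^(-2).

    Identical (bit for bit) to ``gaussian_leup_weights(nnd_sd, 2.0)``.
    """
    return gaussian_leup_weights(nnd_sd, 2.0)


def internal_entropy(probs: Sequence[float]) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 = 0."""
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probabilities")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def internal_energy(model: LEUPModel, dist: LEUPDistribution) -> float:
    """Phenotypic internal energy <S> + (mu/beta) <N> under the fate distribution.

    For mu = 0 this reduces to the mean sensed microenvironmental entropy.
    Satisfies the identity S(x) = beta <S> + mu <N> + ln Z.
    """
    if model.beta == 0 and model.mu != 0:
        raise ValueError("internal energy undefined for beta = 0 with mu != 0")
    mean_s = float(dist.probs @ model.microenv_entropy)
    if model.mu == 0:
        return mean_s
    mean_n = float(dist.probs @ model.neighbor_count)
    return mean_s + (model.mu / model.beta) * mean_n
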