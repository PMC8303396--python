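"""Fluctuation-theorem robustness budget for the differentiation transition.

A tissue-level differentiation step s -> d (pluripotent to differentiated) is
thermodynamically robust when the averaged heat released per transition plus the
internal-entropy change exceeds the pointwise-mutual-information gain:

    <beta' dQ> + <dS> > <di>,

and the maximal ratio of forward to backward (dedifferentiation) transition
probabilities is bounded by exp of the left-minus-right margin.  The heat term
combines anaerobic glycolysis (progenitors) and aerobic respiration
(differentiated cells).

Unit convention: the dimensionless <beta' dQ> is total heat in kJ/mol divided
by the bath temperature in K with the Boltzmann constant set to 1 and the
dimension dropped.  This deliberately reproduces the published arithmetic
(2929.4 / 310 = 9.450); a physically unit-consistent alternative dividing by
R*T (R the molar gas constant) is available behind ``per_rt=True`` and gives a
much larger, differently-scaled number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import internal_entropy

__all__ = [
    "MetabolicScenario",
    "ThermoBudget",
    "total_heat",
    "beta_prime_heat",
    "entropy_change_s_to_d",
    "robustness_check",
    "max_forward_backward_ratio",
    "GAS_CONSTANT_KJ_PER_MOL_K",
]

#: Molar gas constant in kJ/(mol K), for the unit-consistent alternative.
GAS_CONSTANT_KJ_PER_MOL_K = 8.31446261815324e-3


@dataclass(frozen=True)
class MetabolicScenario:
    """Heat released by the two glucose pathways and the bath temperature.

    ``heat_anaerobic`` (kJ/mol): glycolysis/fermentation, the progenitor
    pathway.  ``heat_aerobic`` (kJ/mol): full respiration, the differentiated
    pathway.  ``temperature`` in kelvin.
    """

    heat_anaerobic: float
    heat_aerobic: float
    temperature: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.heat_anaerobic < 0 or self.heat_aerobic < 0:
            raise ValueError("heats must be nonnegative")


@dataclass(frozen=True)
class ThermoBudget:
    """The three averaged terms of the robustness inequality.

    ``beta_prime_dQ``: dimensionless heat term; ``delta_S``: internal-entropy
    change s->d in nats; ``delta_i``: pointwise-mutual-information change in
    nats (0 for equilibrium end states).
    """

    beta_prime_dQ: float
    delta_S: float
    delta_i: float = 0.0

    @property
    def log_ratio_max(self) -> float:
        """ln(p_f^max / p_b) = <beta' dQ> + <dS> - <di>."""
        return self.beta_prime_dQ + self.delta_S - self.delta_i


def total_heat(scenario: MetabolicScenario) -> float:
    """Total heat released over the s -> d journey, kJ/mol."""
    return scenario.heat_anaerobic + scenario.heat_aerobic


def beta_prime_heat(scenario: MetabolicScenario, per_rt: bool = False) -> float:
    """Dimensionless heat term <beta' dQ> = total heat / temperature.

    With ``per_rt=True`` divides by R*T instead (unit-consistent per-molecule
    bookkeeping); note this is NOT the published convention and yields a value
    about 120x larger.
    """
    q = total_heat(scenario)
    if per_rt:
        return q / (GAS_CONSTANT_KJ_PER_MOL_K * scenario.temperature)
    return q / scenario.temperature


def entropy_change_s_to_d(p_differentiated, n_states: int) -> float:
    """<dS> = S(differentiated proportions) - ln(n_states), nats.

    The pluripotent prior is uniform over the ``n_states`` fates (no colour
    preference before differentiation).
    """
    p = list(p_differentiated)
    if len(p) != n_states:
        raise ValueError("n_states must equal the length of p_differentiated")
    return internal_entropy(p) - math.log(n_states)


def robustness_check(budget: ThermoBudget) -> tuple[bool, float]:
    """Whether <beta' dQ> + <dS> > <di> strictly, and the margin (nats).

    Equality is the boundary of the second-law-like inequality and reports
    not-robust.
    """
    margin = budget.log_ratio_max
    return (margin > 0, margin)


def max_forward_backward_ratio(budget: ThermoBudget) -> tuple[float, float]:
    """Maximal forward/backward probability ratio p_f^max / p_b.

    Returns ``(ratio, log_ratio)``; the log form is always finite even when
    the exponential would overflow.
    """
    log_ratio = budget.log_ratio_max
    try:
        ratio = math.exp(log_ratio)
    except OverflowError:
        ratio = math.inf
    return (ratio, log_ratio)
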