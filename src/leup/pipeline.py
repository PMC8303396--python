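"""End-to-end analysis pipeline: fit, thermodynamic budget, landscapes, radii.

``run_pipeline`` chains the four analysis stages on one cone-statistics table
and emits a single machine-readable report:

1. beta fit — KL minimization of the LEUP weights against the observed
   proportions, with a plausibility interval at a DKL threshold;
2. entropy budget — differentiated-state Shannon entropy, the entropy change
   against the uniform pluripotent prior, the metabolic heat term, and the
   fluctuation-theorem robustness margin;
3. entropy-production scenarios — critical radius, its character, and f(R_c)
   for each named parameter set;
4. sensing geometry — per-type hyperuniformity exponents from supplied mean
   sensing radii or variance-model coefficients.

Reports are plain dicts serializable to JSON with canonical key order;
re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import core, inference, production, sensing, thermo

logger = logging.getLogger("leup")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_config", "write_report"]

#: Named entropy-production parameter sets scanned by default: a landscape
#: with an interior minimum (Gamma < 0, dmu > 0), one with an interior
#: maximum (Gamma > 0, dmu < 0), and the double-cone setup using its measured
#: hyperuniformity exponent.
DEFAULT_SCENARIOS: dict[str, dict[str, float | int]] = {
    "minimum_landscape": dict(c0=-1.0, beta_s=3.0, beta_d=3.0, u=1.0, v=1.0, a=1.0, d=2, delta_mu=0.3),
    "maximum_landscape": dict(c0=-1.0, beta_s=1.0, beta_d=3.0, u=1.0, v=1.0, a=1.0, d=2, delta_mu=-0.3),
    "double_cone": dict(c0=-1.0, beta_s=1.0, beta_d=3.0, u=1.0, v=1.0, a=0.440, d=2, delta_mu=0.3),
}


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``stats`` is a packaged fixture name or a CSV path.  ``radii_by_label``
    feeds the sensing-geometry stage directly with mean sensing radii
    (micrometres); alternatively ``coeffs_by_label`` supplies variance-model
    coefficients to solve the radii first.
    """

    stats: str = "kram2010_chicken"
    scenario: dict[str, float] = field(
        default_factory=lambda: dict(
            heat_anaerobic_kj_mol=109.4, heat_aerobic_kj_mol=2820.0, temperature_K=310.0, delta_i=0.0
        )
    )
    entropy_production: dict[str, dict[str, float | int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCENARIOS.items()}
    )
    dkl_threshold: float = 0.01
    beta_bounds: tuple[float, float] = (0.0, 10.0)
    radii_by_label: dict[str, float] | None = field(
        default_factory=lambda: dict(sensing.KRAM_MEAN_SENSING_RADII)
    )
    coeffs_by_label: dict[str, list[float]] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        if "beta_bounds" in raw:
            raw["beta_bounds"] = tuple(raw["beta_bounds"])
        return cls(**raw)


def _load_stats(config: PipelineConfig) -> core.ConeMosaicStats:
    name = config.stats
    if name in core.FIXTURES:
        return core.load_fixture(name)
    path = Path(name)
    if not path.exists():
        raise PipelineError("stats", f"no fixture or CSV file named {name!r}")
    return core.ConeMosaicStats.from_csv(path)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and return the report dict."""
    stats = _load_stats(config)
    logger.info("loaded stats %r: %d cone types", config.stats, len(stats))

    # --- beta fit ---------------------------------------------------------
    try:
        fit = inference.fit_beta(stats, bounds=config.beta_bounds)
        interval = inference.beta_plausible_interval(
            stats, config.dkl_threshold, bounds=config.beta_bounds, fit=fit
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit-beta", str(exc)) from exc
    logger.info("beta_hat=%.4f dkl_min=%.3g", fit.beta_hat, fit.dkl_min)

    # --- thermodynamic budget --------------------------------------------
    try:
        sc = config.scenario
        scenario = thermo.MetabolicScenario(
            heat_anaerobic=float(sc["heat_anaerobic_kj_mol"]),
            heat_aerobic=float(sc["heat_aerobic_kj_mol"]),
            temperature=float(sc["temperature_K"]),
        )
        s_d = core.internal_entropy(stats.proportions)
        delta_s = thermo.entropy_change_s_to_d(stats.proportions, len(stats))
        budget = thermo.ThermoBudget(
            beta_prime_dQ=thermo.beta_prime_heat(scenario),
            delta_S=delta_s,
            delta_i=float(sc.get("delta_i", 0.0)),
        )
        robust, margin = thermo.robustness_check(budget)
        ratio, log_ratio = thermo.max_forward_backward_ratio(budget)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("thermo", str(exc)) from exc

    # --- entropy-production scenarios ------------------------------------
    scenarios_report = {}
    for name, raw in config.entropy_production.items():
        try:
            params = production.EntropyProductionParams(**raw)
            crit = production.critical_radius(params)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("entropy-production", f"scenario {name!r}: {exc}") from exc
        scenarios_report[name] = {
            "params": dict(raw),
            "gamma": production.gamma_coefficient(params),
            "r_c": crit.r_c,
            "kind": crit.kind,
            "f_at_rc": crit.f_at_rc,
        }

    # --- sensing geometry -------------------------------------------------
    sensing_report: dict[str, Any] = {}
    try:
        if config.coeffs_by_label is not None:
            coeffs = {
                lab: sensing.VarianceModelCoeffs(*map(float, v))
                for lab, v in config.coeffs_by_label.items()
            }
            table = sensing.radii_table(stats, coeffs)
        elif config.radii_by_label is not None:
            table = sensing.exponent_table(stats, config.radii_by_label)
        else:
            table = None
        if table is not None:
            sensing_report = {
                "labels": list(table.labels),
                "sensing_radius": [float(x) for x in table.radii],
                "exponent_A": [float(x) for x in table.exponents_a],
                "all_hyperuniform": bool((table.exponents_a < 2).all()),
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("sensing-geometry", str(exc)) from exc

    try:
        version = metadata.version("leup")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"

    return {
        "meta": {"package_version": version, "seed": config.seed, "stats_source": config.stats},
        "beta_fit": {
            "beta_hat": fit.beta_hat,
            "dkl_min": fit.dkl_min,
            "search_bounds": list(fit.search_bounds),
            "dkl_threshold": config.dkl_threshold,
            "beta_interval": list(interval),
        },
        "entropy_budget": {
            "S_differentiated": s_d,
            "delta_S": delta_s,
            "total_heat_kj_mol": thermo.total_heat(scenario),
            "beta_prime_dQ": budget.beta_prime_dQ,
            "delta_i": budget.delta_i,
            "robust": robust,
            "margin": margin,
            "max_forward_backward_ratio": ratio,
            "log_max_forward_backward_ratio": log_ratio,
        },
        "entropy_production": scenarios_report,
        "sensing_geometry": sensing_report,
    }


def default_config() -> PipelineConfig:
    """The packaged avian-fixture configuration."""
    return PipelineConfig()


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Serialize a report to JSON with sorted keys (deterministic bytes)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
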