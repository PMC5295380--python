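"""YAML/JSON configuration for analytic cases and simulation runs.

Two config dialects are understood:

* an *analytic* file with a ``cases`` mapping of named parameter sets
  (reliable/ideal sets give ``AnalyticParams`` fields; adding an
  ``unfair`` block promotes the set to ``UnfairParams``);
* a *simulation* file with a ``simulation`` section mirroring
  :class:`megafund.engine.SimConfig`, plus optional ``dynamics`` and
  ``structuring`` sections for transition matrices, cost schedules and
  validation settings.

All monetary amounts are in millions, as everywhere in the package.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Any

import yaml

from .dynamics import CostSchedule, Phase, TransitionMatrix
from .engine import SimConfig
from .params import AnalyticParams, UnfairParams
from .structuring import FundBehavior

__all__ = [
    "load_config",
    "load_analytic_cases",
    "load_sim_config",
    "sim_config_to_dict",
    "bundled_config_path",
]

_ANALYTIC_FIELDS = {
    "n_assets",
    "n_lemons",
    "n_spvs",
    "spv_size",
    "success_prob",
    "success_value",
    "investment_per_program",
    "senior_share",
    "senior_rate",
    "horizon_years",
    "strict",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a YAML (or JSON — YAML is a superset) config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def _case_from_dict(name: str, raw: dict[str, Any]) -> AnalyticParams | UnfairParams:
    unknown = set(raw) - _ANALYTIC_FIELDS - {"unfair"}
    if unknown:
        raise ValueError(f"case {name!r}: unknown keys {sorted(unknown)}")
    unfair = raw.pop("unfair", None)
    base = AnalyticParams(**raw)
    if unfair is None:
        return base
    return UnfairParams(
        base=base,
        n_clean_spvs=unfair["n_clean_spvs"],
        n_toxic_spvs=unfair["n_toxic_spvs"],
        lemons_per_clean_spv=unfair["lemons_per_clean_spv"],
        lemons_per_toxic_spv=unfair["lemons_per_toxic_spv"],
    )


def load_analytic_cases(path: str | Path) -> dict[str, AnalyticParams | UnfairParams]:
    """Read the named parameter sets from an analytic config file."""
    data = load_config(path)
    if "cases" not in data:
        raise ValueError(f"{path}: analytic config needs a 'cases' mapping")
    defaults = data.get("defaults", {})
    cases = {}
    for name, raw in data["cases"].items():
        merged = {**defaults, **(raw or {})}
        cases[name] = _case_from_dict(name, merged)
    return cases


def _matrix_from_dict(raw: dict[str, Any]) -> TransitionMatrix:
    if "probs" in raw:
        return TransitionMatrix(raw["probs"])
    return TransitionMatrix.from_rates(
        preclinical_advance=raw["preclinical_advance"],
        preclinical_fail=raw["preclinical_fail"],
        phase1_advance=raw["phase1_advance"],
        phase1_fail=raw["phase1_fail"],
    )


def _costs_from_dict(raw: dict[str, Any]) -> CostSchedule:
    kwargs: dict[str, Any] = {}
    for key in ("upfront", "sale_value"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("periodic", "milestone"):
        if key in raw:
            kwargs[key] = {Phase[k.upper()]: v for k, v in raw[key].items()}
    return CostSchedule(**kwargs)


def load_sim_config(path: str | Path, **overrides: Any) -> SimConfig:
    """Build a :class:`SimConfig` from a simulation config file.

    Keyword overrides (e.g. ``seed=...``, ``n_paths=...``) take
    precedence over file values.
    """
    data = load_config(path)
    sim = dict(data.get("simulation", {}))
    dynamics = data.get("dynamics", {})
    structuring = data.get("structuring", {})

    kwargs: dict[str, Any] = {}
    kwargs.update(sim)
    if "behavior" in structuring:
        kwargs["behavior"] = structuring["behavior"]
    for key in (
        "validation_fraction",
        "toxic_fraction",
        "detection_scale",
        "false_positive_rate",
        "uplift_slope",
    ):
        if key in structuring:
            kwargs[key] = structuring[key]
    if "nonlemon_matrix" in dynamics:
        kwargs["nonlemon_matrix"] = _matrix_from_dict(dynamics["nonlemon_matrix"])
    if "lemon_matrix" in dynamics:
        kwargs["lemon_matrix"] = _matrix_from_dict(dynamics["lemon_matrix"])
    if "lemon_severity" in dynamics:
        kwargs["lemon_severity"] = dynamics["lemon_severity"]
    if "costs" in dynamics:
        kwargs["costs"] = _costs_from_dict(dynamics["costs"])
    kwargs.update(overrides)
    if "behavior" in kwargs:
        kwargs["behavior"] = FundBehavior(kwargs["behavior"])
    try:
        return SimConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"invalid simulation config {path}: {exc}") from exc


def sim_config_to_dict(config: SimConfig) -> dict[str, Any]:
    """JSON-serializable snapshot of a simulation config (for manifests)."""
    nonlemon, lemon = config.matrices()
    return {
        "simulation": {
            "n_assets": config.n_assets,
            "lemon_fraction": config.lemon_fraction,
            "behavior": FundBehavior(config.behavior).value,
            "validation_fraction": config.validation_fraction,
            "n_paths": config.n_paths,
            "seed": config.seed,
            "horizon_semesters": config.horizon_semesters,
            "investment_per_program": config.investment_per_program,
            "senior_share": config.senior_share,
            "senior_rate": config.senior_rate,
            "cash_rate_semester": config.cash_rate_semester,
            "waterfall_mode": config.waterfall_mode,
            "uplift_slope": config.uplift_slope,
            "toxic_fraction": config.toxic_fraction,
            "lemon_severity": config.lemon_severity,
            "n_spvs": config.n_spvs,
            "spv_size": config.spv_size,
            "promise_years": config.promise_years,
        },
        "dynamics": {
            "nonlemon_matrix_effective": nonlemon.probs.tolist(),
            "lemon_matrix_effective": lemon.probs.tolist(),
            "costs": {
                "upfront": config.costs.upfront,
                "periodic": {p.name.lower(): c for p, c in config.costs.periodic.items()},
                "milestone": {p.name.lower(): c for p, c in config.costs.milestone.items()},
                "sale_value": config.costs.sale_value,
            },
        },
    }


def bundled_config_path(name: str) -> Path:
    """Path to a config shipped with the package (``table2.yaml``,
    ``figure1.yaml``)."""
    ref = importlib.resources.files("megafund") / "configs" / name
    path = Path(str(ref))
    if not path.exists():
        raise FileNotFoundError(f"no bundled config named {name!r}")
    return path


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
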