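"""YAML/JSON round-tripping of the package's configuration objects."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .markov import MarkovParameters, PriceSchedule
from .psa import (
    Beta,
    CoxMappedRRR,
    Gamma,
    LdlMappedRRR,
    ParameterDistributions,
    PointMass,
    TruncNormal,
)
from .scenarios import ScenarioSpec, builtin_schedules

__all__ = [
    "load_cohort_spec",
    "save_cohort_spec",
    "load_markov_parameters",
    "save_markov_parameters",
    "load_distributions",
    "save_distributions",
    "load_scenario_grid",
]

_DIST_TYPES = {
    "beta": Beta,
    "gamma": Gamma,
    "truncnormal": TruncNormal,
    "pointmass": PointMass,
    "ldl_mapped_rrr": LdlMappedRRR,
    "cox_mapped_rrr": CoxMappedRRR,
}
_DIST_NAMES = {v: k for k, v in _DIST_TYPES.items()}


def save_cohort_spec(spec: CohortSpec, path) -> None:
    data = asdict(spec)
    data["covariate_prevalences"] = dict(spec.covariate_prevalences)
    data["ldl_change_bounds"] = list(spec.ldl_change_bounds)
    data["followup_days_range"] = list(spec.followup_days_range)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_cohort_spec(path) -> CohortSpec:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("ldl_change_bounds", "followup_days_range"):
        if key in data:
            data[key] = tuple(data[key])
    spec = CohortSpec(**data)
    spec.validate()
    return spec


def _price_to_dict(price: PriceSchedule) -> dict:
    return {"name": price.name, "annual_cost_by_year": list(price.annual_cost_by_year)}


def _price_from_obj(obj) -> PriceSchedule:
    if isinstance(obj, str):
        catalog = builtin_schedules()
        if obj not in catalog:
            raise ValueError(
                f"unknown price schedule {obj!r}; known: {sorted(catalog)}"
            )
        return catalog[obj]
    return PriceSchedule(obj["name"], tuple(float(c) for c in obj["annual_cost_by_year"]))


def save_markov_parameters(params: MarkovParameters, path) -> None:
    data = asdict(params)
    data["price"] = _price_to_dict(params.price)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_markov_parameters(path) -> MarkovParameters:
    data = yaml.safe_load(Path(path).read_text())
    if "price" in data:
        data["price"] = _price_from_obj(data["price"])
    params = MarkovParameters(**data)
    params.validate()
    return params


def _dist_to_dict(dist) -> dict:
    out = {"dist": _DIST_NAMES[type(dist)]}
    out.update(asdict(dist))
    return out


def _dist_from_dict(data: dict):
    kind = data.pop("dist")
    if kind not in _DIST_TYPES:
        raise ValueError(f"unknown distribution kind {kind!r}")
    return _DIST_TYPES[kind](**data)


def save_distributions(dists: ParameterDistributions, path) -> None:
    data = {
        name: _dist_to_dict(getattr(dists, name))
        for name in ParameterDistributions._DRAW_ORDER
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_distributions(path) -> ParameterDistributions:
    data = yaml.safe_load(Path(path).read_text())
    return ParameterDistributions(
        **{name: _dist_from_dict(dict(spec)) for name, spec in data.items()}
    )


def load_scenario_grid(path) -> list[ScenarioSpec]:
    """Read a scenario grid: a YAML list of scenario mappings."""
    data = yaml.safe_load(Path(path).read_text())
    specs = []
    for item in data:
        item = dict(item)
        item["price_schedule"] = _price_from_obj(item["price_schedule"])
        if "wtps" in item:
            item["wtps"] = tuple(float(w) for w in item["wtps"])
        spec = ScenarioSpec(**item)
        spec.validate()
        specs.append(spec)
    return specs
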