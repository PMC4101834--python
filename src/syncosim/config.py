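"""Structured parameter-file interface (YAML).

A configuration file has the sections ``clinical``, ``costs``, ``scenarios``,
``life_table_path``, ``sensitivity`` and ``psa``.  Omitted sections fall back
to the bundled base case.  `save_config` writes a canonical serialisation
(sorted keys, stable float formatting), so load -> save round-trips a
canonically written file bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import datasets
from .params import (ClinicalParameters, CostParameters, LifeTable,
                     ScenarioItem, ScenarioProfile)

__all__ = ["RunBundle", "load_config", "save_config", "default_bundle",
           "CONFIG_SCHEMA"]

#: Shipped schema: section -> {key: type description}.  Validation in
#: load_config is structural (unknown keys rejected, types checked by the
#: parameter classes themselves).
CONFIG_SCHEMA = {
    "clinical": {f: "number" for f in ClinicalParameters.__dataclass_fields__},
    "costs": {f: "number" for f in CostParameters.__dataclass_fields__},
    "scenarios": {"<name>": {"items": "list of [test_name, unit_price, "
                             "fraction_of_patients]",
                             "printed_total": "number or null"}},
    "life_table_path": "path to two-column CSV (age, annual_death_prob) "
                       "or null for the bundled synthetic table",
    "sensitivity": {"ranges": "list of [parameter, low, high]"},
    "psa": {"n_draws": "int", "seed": "int",
            "beta_ess": "number", "interval_ratio": "number"},
}


@dataclass(frozen=True)
class RunBundle:
    """Everything a model run needs, as loaded from one parameter file."""

    clinical: ClinicalParameters
    costs: CostParameters
    scenarios: dict[str, ScenarioProfile]
    life_table: LifeTable
    life_table_path: str | None = None
    sensitivity_ranges: list[tuple[str, float, float]] | None = None
    psa_settings: dict = field(default_factory=dict)


def default_bundle(horizon_years: float = 30.0) -> RunBundle:
    """The bundled base case as a RunBundle."""
    return RunBundle(
        clinical=datasets.base_clinical(horizon_years),
        costs=datasets.base_costs(),
        scenarios=datasets.scenario_profiles(),
        life_table=datasets.default_life_table(),
    )


def _check_section(name: str, mapping: dict, allowed) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ValueError(f"config section {name!r}: unknown key(s) {sorted(unknown)}")


def load_config(path) -> RunBundle:
    """Load and validate a YAML parameter file (see module docstring)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    _check_section("<top level>", raw, CONFIG_SCHEMA)

    clin_raw = raw.get("clinical", {}) or {}
    _check_section("clinical", clin_raw, ClinicalParameters.__dataclass_fields__)
    clinical = ClinicalParameters(**clin_raw)

    costs_raw = raw.get("costs", {}) or {}
    _check_section("costs", costs_raw, CostParameters.__dataclass_fields__)
    costs = CostParameters(**costs_raw)

    scen_raw = raw.get("scenarios")
    if scen_raw:
        scenarios = {}
        for name, body in scen_raw.items():
            _check_section(f"scenarios[{name}]", body, ("items", "printed_total"))
            items = tuple(ScenarioItem(str(t), float(p), float(f))
                          for t, p, f in body.get("items", []))
            scenarios[name] = ScenarioProfile(
                name=name, items=items,
                printed_total=body.get("printed_total"))
    else:
        scenarios = datasets.scenario_profiles()

    lt_path = raw.get("life_table_path")
    if lt_path:
        lt_file = Path(lt_path)
        if not lt_file.is_absolute():
            lt_file = path.parent / lt_file
        if not lt_file.exists():
            raise FileNotFoundError(f"life-table file not found: {lt_file}")
        life_table = LifeTable.from_file(lt_file)
    else:
        life_table = datasets.default_life_table()

    sens = raw.get("sensitivity") or {}
    _check_section("sensitivity", sens, ("ranges",))
    ranges = ([(str(n), float(lo), float(hi)) for n, lo, hi in sens["ranges"]]
              if sens.get("ranges") else None)

    psa_settings = raw.get("psa") or {}
    _check_section("psa", psa_settings, CONFIG_SCHEMA["psa"])

    return RunBundle(clinical=clinical, costs=costs, scenarios=scenarios,
                     life_table=life_table, life_table_path=lt_path,
                     sensitivity_ranges=ranges, psa_settings=dict(psa_settings))


def save_config(bundle: RunBundle, path) -> None:
    """Write a bundle as a canonical YAML parameter file.

    The bundled life table is referenced by ``life_table_path`` when one was
    given; otherwise the section is null and loading falls back to the
    bundled synthetic table.
    """
    doc = {
        "clinical": _numbers(asdict(bundle.clinical)),
        "costs": _numbers(asdict(bundle.costs)),
        "scenarios": {
            name: {
                "items": [[it.test_name, float(it.unit_price),
                           float(it.fraction_of_patients)]
                          for it in prof.items],
                "printed_total": (None if prof.printed_total is None
                                  else float(prof.printed_total)),
            }
            for name, prof in sorted(bundle.scenarios.items())
        },
        "life_table_path": bundle.life_table_path,
        "sensitivity": {"ranges": ([[n, float(lo), float(hi)] for n, lo, hi
                                    in bundle.sensitivity_ranges]
                                   if bundle.sensitivity_ranges else None)},
        "psa": bundle.psa_settings or None,
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=True, default_flow_style=None))


def _numbers(d: dict) -> dict:
    return {k: (float(v) if isinstance(v, (int, float)) else v)
            for k, v in d.items()}
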