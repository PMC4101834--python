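"""Report generation: headline-count/cost tables and validation reports.

The base-case report mirrors the structure of the published results table:
shared count rows (diagnosed, undiagnosed-and-alive, episodes, injuries),
the cost-component rows of the base scenario, and one total-cost row per
workup scenario, with ILR / CDP / savings columns at both the 3-year and
lifetime horizons.  Costs are formatted to whole EUR and probabilities to 4
decimals at the presentation layer only.

All writers use fixed float formatting and sorted ordering, so an identical
configuration and seed produce byte-identical CSV output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunBundle
from .engine import ArmSpec, run_cohort, summarize
from .model import ModelContext
from .params import round_half_up

__all__ = ["base_case_report", "write_report", "validation_report"]

log = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.6f"


def _context(bundle: RunBundle, scenario: str, horizon: float,
             **flags) -> ModelContext:
    return ModelContext(
        clinical=bundle.clinical.with_(horizon_years=horizon),
        costs=bundle.costs,
        profile=bundle.scenarios[scenario],
        life_table=bundle.life_table,
        **flags,
    )


def base_case_report(bundle: RunBundle, horizons=(30.0, 3.0),
                     base_scenario: str = "Sousa Pedro",
                     **flags) -> pd.DataFrame:
    """Headline table across all scenarios and horizons.

    Count rows and the device/trauma cost components come from the base
    scenario (they are identical across workup scenarios); each scenario
    contributes its own total-cost row.
    """
    rows: dict[str, dict[str, float]] = {}

    def put(row: str, col: str, value: float) -> None:
        rows.setdefault(row, {})[col] = value

    for horizon in horizons:
        label = "lifetime" if horizon >= 29 else f"{horizon:g}y"
        results = {name: _context(bundle, name, horizon, **flags).run()
                   for name in bundle.scenarios}
        base = results[base_scenario]
        for arm, trace, ledger in (("ILR", base.ilr_trace, base.ilr_ledger),
                                   ("CDP", base.cdp_trace, base.cdp_ledger)):
            col = f"{arm} {label}"
            s = summarize(trace)
            put("Number of patients diagnosed", col, s.diagnosed_total)
            put("Number of patients undiagnosed and alive", col,
                s.undiagnosed_alive)
            put("Total syncope episodes", col, s.episodes)
            put("Number of injuries (major and minor)", col, s.injuries)
            totals = ledger.component_totals()
            put("Costs - device acquisition", col,
                round_half_up(totals["device_acquisition"]))
            put("Costs - device-related expenses", col,
                round_half_up(totals["implantation"] + totals["followup"]
                              + totals["explantation"]))
            put("Costs - syncope admissions", col,
                round_half_up(totals["trauma"]))
            put("Costs - diagnostic tests", col,
                round_half_up(totals["workup"]))
        for name, res in sorted(results.items()):
            put(f"Costs - total ({name})", f"ILR {label}",
                round_half_up(res.comparison.ilr_total))
            put(f"Costs - total ({name})", f"CDP {label}",
                round_half_up(res.comparison.cdp_total))
    df = pd.DataFrame(rows).T
    for horizon in horizons:
        label = "lifetime" if horizon >= 29 else f"{horizon:g}y"
        df[f"savings {label}"] = df[f"CDP {label}"] - df[f"ILR {label}"]
    return df


def write_report(df: pd.DataFrame, outdir, stem: str = "base_case") -> dict:
    """Write a report table as CSV + JSON; returns the JSON document."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / f"{stem}.csv", float_format=CSV_FLOAT_FORMAT)
    doc = json.loads(df.to_json(orient="index"))
    (outdir / f"{stem}.json").write_text(json.dumps(doc, indent=2,
                                                    sort_keys=True))
    return doc


def validation_report(bundle: RunBundle, n_patients: int = 100_000,
                      seed: int = 0, horizon: float = 3.0) -> dict:
    """Cross-check the cohort engine against its stochastic counterparts.

    Runs the patient-level microsimulation at ``n_patients`` per arm and
    compares cumulative diagnosed/dead/episode counts with the cohort
    expectation in Monte-Carlo standard-error units; also checks the
    zero-mortality geometric closed form and state-occupancy conservation.
    """
    from . import synthetic

    clin = bundle.clinical.with_(horizon_years=horizon)
    lt = bundle.life_table
    out: dict = {"n_patients": n_patients, "seed": seed,
                 "horizon_years": horizon, "checks": {}}
    rng = np.random.default_rng(seed)
    for spec in (ArmSpec.ilr(clin), ArmSpec.cdp(clin)):
        trace = run_cohort(clin, spec, lt)
        hist = synthetic.simulate_patients(clin, spec, lt, n_patients, rng)
        checks = {}
        for label, expected_total, observed in (
            ("diagnosed", trace.new_diagnosed.sum() / clin.cohort_size,
             hist.diagnosis.any(axis=1).mean()),
            ("dead", trace.new_dead.sum() / clin.cohort_size,
             hist.death.any(axis=1).mean()),
            ("episodes", trace.episodes.sum() / clin.cohort_size,
             hist.syncope.sum(axis=1).mean()),
        ):
            if label == "episodes":
                se = hist.syncope.sum(axis=1).std(ddof=1) / np.sqrt(n_patients)
            else:
                p = expected_total
                se = np.sqrt(max(p * (1 - p), 1e-12) / n_patients)
            z = (observed - expected_total) / se if se > 0 else 0.0
            checks[label] = {"expected_per_patient": float(expected_total),
                             "observed_per_patient": float(observed),
                             "z": float(z), "pass": bool(abs(z) <= 3.0)}
        # conservation of occupancy
        cons = np.max(np.abs(
            trace.undiagnosed[1:] + trace.cumulative_diagnosed
            + trace.cumulative_dead - clin.cohort_size))
        checks["conservation_max_abs_error"] = {"value": float(cons),
                                                "pass": bool(cons < 1e-9)}
        out["checks"][spec.arm_id.value] = checks

    # zero-mortality geometric closed form (constant-yield arm)
    from .params import LifeTable

    flat = LifeTable([0.0, 120.0], [0.0, 0.0])
    spec = ArmSpec.cdp(clin)
    trace0 = run_cohort(clin, spec, flat)
    sigma_c = clin.annual_syncope_rate * clin.cycle_length_years
    T = clin.n_cycles
    closed = clin.cohort_size * (
        1.0 - (1.0 - sigma_c * clin.diagnosis_prob_cdp) ** T)
    err = abs(trace0.new_diagnosed.sum() - closed)
    out["checks"]["geometric_closed_form_abs_error"] = {
        "value": float(err), "pass": bool(err < 1e-9 * clin.cohort_size)}
    out["all_pass"] = all(
        c.get("pass", True) for arm in out["checks"].values()
        for c in (arm.values() if isinstance(arm, dict) and "value" not in arm
                  else [arm]))
    return out
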