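"""One-way (tornado), threshold and probabilistic sensitivity analysis.

All analyses evaluate the lifetime (30-year) model through a
:class:`~syncosim.model.ModelContext` with ``recompute_trauma=True``, so the
per-event trauma cost responds to overrides of the tariffs and of the
injury/severity probabilities.

Probabilistic sensitivity analysis (PSA): each uncertain parameter is given
a distribution appropriate to its support — lognormal for the death hazard
ratio and the syncope recurrence rate, gamma for unit costs, beta for
probabilities.  The source dispersions are not published, so the defaults
are derived from the one-way ranges: gamma/lognormal distributions are
moment-matched so that their central 95% interval is [base/2, 2 x base]
(lognormal keeps the base as median), and beta distributions take the base
as mean with an effective sample size of 100.  Per-diagnostic-test
uncertainty is aggregated into a single gamma on the scenario's workup
total.  All dispersions are overridable.  Draws are independent across
parameters and consumed in the fixed order of the spec list, so a seed
reproduces a run exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelContext
from .params import expected_trauma_cost

__all__ = [
    "TornadoEntry",
    "UncertaintySpec",
    "PsaResult",
    "ThresholdResult",
    "one_way",
    "tornado",
    "default_tornado_ranges",
    "threshold_sweep",
    "default_psa_specs",
    "draw_parameters",
    "psa",
]

log = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)


# --------------------------------------------------------------------------
# one-way / tornado

@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram (per-patient lifetime savings)."""

    parameter: str
    base_value: float
    low: float
    high: float
    savings_at_low: float
    savings_at_high: float

    @property
    def width(self) -> float:
        return abs(self.savings_at_high - self.savings_at_low)


def one_way(ctx: ModelContext, parameter: str, low: float, high: float,
            base_value: float | None = None) -> TornadoEntry:
    """Evaluate per-patient lifetime savings with one parameter at each bound."""
    ctx = ctx.with_(recompute_trauma=True)
    if not (min(low, high) <= _base_value(ctx, parameter, base_value)
            <= max(low, high)):
        raise ValueError(
            f"{parameter}: bounds [{low}, {high}] do not bracket the base value")
    s_low = ctx.run({parameter: low}).comparison.per_patient_savings
    s_high = ctx.run({parameter: high}).comparison.per_patient_savings
    if not (math.isfinite(s_low) and math.isfinite(s_high)):
        raise ValueError(f"{parameter}: non-finite savings")
    return TornadoEntry(parameter, _base_value(ctx, parameter, base_value),
                        low, high, s_low, s_high)


def _base_value(ctx: ModelContext, parameter: str,
                explicit: float | None) -> float:
    if explicit is not None:
        return explicit
    if parameter == "workup_cost":
        return ctx.profile.canonical_workup_cost
    for obj in (ctx.clinical, ctx.costs):
        if hasattr(obj, parameter):
            return float(getattr(obj, parameter))
    raise KeyError(f"unknown parameter {parameter!r}")


def tornado(ctx: ModelContext,
            entries: list[tuple[str, float, float]] | None = None) -> list[TornadoEntry]:
    """One-way analysis over all entries, sorted by descending bar width.

    Ties are broken by parameter name, so the ordering is invariant to the
    input order.
    """
    if entries is None:
        entries = default_tornado_ranges(ctx)
    if not entries:
        raise ValueError("at least one tornado entry is required")
    bars = [one_way(ctx, name, lo, hi) for name, lo, hi in entries]
    return sorted(bars, key=lambda b: (-b.width, b.parameter))


def default_tornado_ranges(ctx: ModelContext) -> list[tuple[str, float, float]]:
    """Default one-way ranges: halve/double the base value, except where a
    published alternative source pins the bound (ILR yield upper bound 0.78,
    syncope rate upper bound 0.81/yr, injury probability lower bound 0.25)."""
    clin, costs = ctx.clinical, ctx.costs
    half_double = lambda v: (v / 2.0, min(v * 2.0, 1.0))
    return [
        ("diagnosis_prob_ilr", clin.diagnosis_prob_cdp, 0.78),
        ("diagnosis_prob_cdp", clin.diagnosis_prob_cdp / 2,
         clin.diagnosis_prob_cdp * 2),
        ("annual_syncope_rate", clin.annual_syncope_rate / 2, 0.81),
        ("mortality_hazard_ratio", clin.mortality_hazard_ratio / 2,
         clin.mortality_hazard_ratio * 2),
        ("injury_prob_per_event", 0.25, min(clin.injury_prob_per_event * 2, 1.0)),
        ("severe_injury_fraction", *half_double(clin.severe_injury_fraction)),
        ("minor_trauma_tariff", costs.minor_trauma_tariff / 2,
         costs.minor_trauma_tariff * 2),
        ("major_trauma_tariff", costs.major_trauma_tariff / 2,
         costs.major_trauma_tariff * 2),
        ("device_acquisition", costs.device_acquisition / 2,
         costs.device_acquisition * 2),
        ("implantation", costs.implantation / 2, costs.implantation * 2),
        ("workup_cost", ctx.profile.canonical_workup_cost / 2,
         ctx.profile.canonical_workup_cost * 2),
    ]


def tornado_to_frame(bars: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": b.parameter, "base_value": b.base_value,
        "low": b.low, "high": b.high,
        "savings_at_low": b.savings_at_low,
        "savings_at_high": b.savings_at_high,
        "width": b.width,
    } for b in bars])


# --------------------------------------------------------------------------
# threshold sweep over the ILR diagnostic yield

@dataclass(frozen=True)
class ThresholdResult:
    """Lifetime cohort savings as a function of the ILR diagnostic yield."""

    deltas: np.ndarray
    savings: np.ndarray
    break_even: float | None          # interpolated yield where savings = 0
    meets_absolute_rule: bool         # base-case yield > 0.35
    meets_incremental_rule: bool      # yield - conventional yield >= 0.175

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"diagnosis_prob_ilr": self.deltas,
                             "lifetime_savings": self.savings})


def threshold_sweep(ctx: ModelContext,
                    grid: np.ndarray | None = None) -> ThresholdResult:
    """Sweep the ILR per-event yield over a grid, everything else base-case.

    The break-even yield is found by linear interpolation between the grid
    points bracketing the (single, by monotonicity) sign change; ``None``
    when the savings never change sign on the grid.
    """
    ctx = ctx.with_(recompute_trauma=True)
    if grid is None:
        grid = np.arange(0.125, 0.7801, 0.005)
    grid = np.asarray(grid, float)
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("grid values must be probabilities in [0, 1]")
    savings = np.array([
        ctx.run({"diagnosis_prob_ilr": float(d)}).comparison.savings
        for d in grid])
    break_even = None
    sign_changes = np.nonzero(np.diff(np.sign(savings)) != 0)[0]
    if sign_changes.size:
        i = int(sign_changes[0])
        x0, x1 = grid[i], grid[i + 1]
        y0, y1 = savings[i], savings[i + 1]
        break_even = float(x0 - y0 * (x1 - x0) / (y1 - y0))
    base_delta = ctx.clinical.diagnosis_prob_ilr
    return ThresholdResult(
        deltas=grid, savings=savings, break_even=break_even,
        meets_absolute_rule=base_delta > 0.35,
        meets_incremental_rule=(base_delta - ctx.clinical.diagnosis_prob_cdp)
        >= 0.175,
    )


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass(frozen=True)
class UncertaintySpec:
    """Distributional assumption for one uncertain parameter.

    ``family`` is one of lognormal / gamma / beta / degenerate.  The
    dispersion descriptor depends on the family: ``sigma`` (log-scale SD,
    base value kept as the median) for lognormal, ``shape`` (mean fixed at
    the base value) for gamma, ``ess`` (effective sample size, mean fixed at
    the base value) for beta.
    """

    name: str
    family: str
    base: float
    sigma: float | None = None
    shape: float | None = None
    ess: float | None = None
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        fam = self.family
        if fam == "lognormal":
            if self.base <= 0 or not self.sigma or self.sigma <= 0:
                raise ValueError(f"{self.name}: lognormal needs base > 0 and sigma > 0")
        elif fam == "gamma":
            if self.base < 0 or not self.shape or self.shape <= 0:
                raise ValueError(f"{self.name}: gamma needs base >= 0 and shape > 0")
        elif fam == "beta":
            if not (0.0 <= self.base <= 1.0) or not self.ess or self.ess <= 0:
                raise ValueError(f"{self.name}: beta needs base in [0,1] and ess > 0")
        elif fam != "degenerate":
            raise ValueError(f"{self.name}: unknown family {fam!r}")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "degenerate":
            out = np.full(size, self.base)
        elif self.family == "lognormal":
            out = rng.lognormal(mean=np.log(self.base), sigma=self.sigma,
                                size=size)
        elif self.family == "gamma":
            if self.base == 0:
                out = np.zeros(size)
            else:
                out = rng.gamma(shape=self.shape,
                                scale=self.base / self.shape, size=size)
        else:  # beta
            if self.base in (0.0, 1.0):
                out = np.full(size, self.base)
            else:
                a = self.base * self.ess
                b = (1.0 - self.base) * self.ess
                out = rng.beta(a, b, size=size)
        return np.clip(out, self.lower, self.upper)

    # ---- constructors implementing the default dispersion derivation ----

    @classmethod
    def lognormal_halved_doubled(cls, name: str, base: float,
                                 **kw) -> "UncertaintySpec":
        """Lognormal with median = base and 95% interval [base/2, 2 x base]."""
        return cls(name, "lognormal", base, sigma=math.log(2.0) / _Z95, **kw)

    @classmethod
    def gamma_halved_doubled(cls, name: str, base: float) -> "UncertaintySpec":
        """Gamma with mean = base and a 97.5%/2.5% quantile ratio of 4."""
        return cls(name, "gamma", base, shape=_gamma_shape_for_ratio(4.0))

    @classmethod
    def beta_mean_ess(cls, name: str, base: float,
                      ess: float = 100.0) -> "UncertaintySpec":
        return cls(name, "beta", base, ess=ess)

    @classmethod
    def degenerate(cls, name: str, base: float) -> "UncertaintySpec":
        return cls(name, "degenerate", base)


def _gamma_shape_for_ratio(ratio: float) -> float:
    """Shape k such that gamma(k)'s 97.5%/2.5% quantile ratio equals ``ratio``."""
    f = lambda k: (stats.gamma.ppf(0.975, k) / stats.gamma.ppf(0.025, k)
                   - ratio)
    return float(optimize.brentq(f, 0.5, 500.0, xtol=1e-10))


def default_psa_specs(ctx: ModelContext) -> list[UncertaintySpec]:
    """Default uncertain-parameter set (fixed order; see module docstring)."""
    clin, costs = ctx.clinical, ctx.costs
    S = UncertaintySpec
    return [
        # upper truncation keeps the quarterly competing-risk fractions
        # feasible at the oldest model ages (well beyond the one-way bound)
        S.lognormal_halved_doubled("mortality_hazard_ratio",
                                   clin.mortality_hazard_ratio, upper=4.0),
        S.lognormal_halved_doubled("annual_syncope_rate",
                                   clin.annual_syncope_rate,
                                   upper=(1.0 / clin.cycle_length_years) - 1e-9),
        S.beta_mean_ess("diagnosis_prob_ilr", clin.diagnosis_prob_ilr),
        S.beta_mean_ess("diagnosis_prob_cdp", clin.diagnosis_prob_cdp),
        S.beta_mean_ess("injury_prob_per_event", clin.injury_prob_per_event),
        S.beta_mean_ess("severe_injury_fraction", clin.severe_injury_fraction),
        S.gamma_halved_doubled("device_acquisition", costs.device_acquisition),
        S.gamma_halved_doubled("implantation", costs.implantation),
        S.gamma_halved_doubled("explantation", costs.explantation),
        S.gamma_halved_doubled("followup_visit", costs.followup_visit),
        S.gamma_halved_doubled("minor_trauma_tariff", costs.minor_trauma_tariff),
        S.gamma_halved_doubled("major_trauma_tariff", costs.major_trauma_tariff),
        S.gamma_halved_doubled("workup_cost", ctx.profile.canonical_workup_cost),
    ]


def draw_parameters(specs: list[UncertaintySpec],
                    seed: int | np.random.Generator,
                    size: int = 1) -> dict[str, np.ndarray]:
    """Independent draws for every spec, ``size`` values each.

    One seeded generator; draws are consumed in spec-list order, so the same
    seed and spec list reproduce the same values on any platform.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {s.name: s.draw(rng, size) for s in specs}


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo distribution of lifetime cohort savings (ILR vs CDP)."""

    n_draws: int
    seed: int | None
    scenario: str
    cohort_size: float
    savings: np.ndarray                 # per-draw lifetime cohort savings, EUR
    mean_savings: float
    fraction_cost_saving: float
    quantiles: dict[float, float]
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    @property
    def per_patient_mean_savings(self) -> float:
        return self.mean_savings / self.cohort_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"draw": np.arange(self.n_draws),
                             "savings": self.savings})


def psa(ctx: ModelContext, specs: list[UncertaintySpec] | None = None,
        n_draws: int = 10_000, seed: int | None = 0,
        quantile_probs=(0.025, 0.25, 0.5, 0.75, 0.975),
        n_bins: int = 40) -> PsaResult:
    """Probabilistic sensitivity analysis over the lifetime model.

    Runs the full two-arm model once per draw and collects the distribution
    of total-cohort savings.  A per-draw model failure aborts with the draw
    index logged.  Repeat with a different ``ctx.profile`` to cover the five
    workup scenarios.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ctx = ctx.with_(recompute_trauma=True)
    if specs is None:
        specs = default_psa_specs(ctx)
    draws = draw_parameters(specs, np.random.default_rng(seed), n_draws)
    savings = np.empty(n_draws)
    for i in range(n_draws):
        overrides = {name: float(vals[i]) for name, vals in draws.items()}
        try:
            savings[i] = ctx.run(overrides).comparison.savings
        except Exception:
            log.error("PSA draw %d failed with overrides %r", i, overrides)
            raise
    counts, edges = np.histogram(savings, bins=n_bins)
    return PsaResult(
        n_draws=n_draws,
        seed=seed,
        scenario=ctx.profile.name,
        cohort_size=ctx.clinical.cohort_size,
        savings=savings,
        mean_savings=float(savings.mean()),
        fraction_cost_saving=float(np.mean(savings > 0)),
        quantiles={float(p): float(np.quantile(savings, p))
                   for p in quantile_probs},
        histogram_counts=counts,
        histogram_edges=edges,
    )
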