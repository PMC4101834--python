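"""Bundled base-case fixtures: scenario workup tables and a synthetic life table.

The five workup scenarios reproduce the published diagnostic-test frequency
table (fraction of syncope patients receiving each test x Portuguese unit
price), one scenario per source study.  Tests with no national unit price
(adenosine triphosphate test, unspecified "others") are excluded, mirroring
the costing rule of the source analysis.  Each scenario carries the printed
per-event total, which the engine treats as canonical.

The default life table is a synthetic Gompertz-Makeham fixture — official
national age-specific mortality is an external source not shipped here — and
is calibrated so q(61) ~= 0.010, rising to ~0.15 by age 90.  Any real life
table can be substituted through :meth:`syncosim.params.LifeTable.from_file`.
"""

from __future__ import annotations

from .params import ClinicalParameters, CostParameters, LifeTable, ScenarioProfile

__all__ = [
    "base_clinical",
    "base_costs",
    "scenario_profiles",
    "default_life_table",
    "SCENARIO_NAMES",
    "GOMPERTZ_MAKEHAM_DEFAULTS",
]

SCENARIO_NAMES = ("Sousa Pedro", "Edvardsson", "Baron-Esquivias",
                  "Brignole", "Farwell")

#: Makeham level a (1/yr), Gompertz scale b (1/yr) and slope c (1/yr) of the
#: bundled synthetic life table, with its age range.  Calibrated by least
#: squares against approximate Portuguese both-sex annual death probabilities
#: circa 2010 with the entry level pinned at q(61) ~= 0.010: the fit gives
#: q(70) ~= 0.019, q(80) ~= 0.052, q(90) ~= 0.169.
GOMPERTZ_MAKEHAM_DEFAULTS = dict(a=6.278e-3, b=1.124e-6, c=0.13309,
                                 min_age=50, max_age=100)

# (test name, unit price EUR, fraction of patients) per scenario.
_SOUSA_PEDRO = (
    ("Standard electrocardiogram", 6.50, 1.00),
    ("Echocardiography", 53.20, 0.722),
    ("Overload echocardiography", 85.30, 0.016),
    ("In-hospital ECG monitoring", 124.70, 0.612),
    ("Exercise testing", 32.10, 0.196),
    ("MRI or CT scan", 97.45, 0.016),
    ("Electroencephalography", 58.80, 0.012),
    ("Carotid sinus massage", 6.50, 0.029),
    ("Carotid echo-doppler", 23.17, 0.127),
    ("TILT test", 124.10, 0.159),
    ("External loop recording", 47.30, 0.118),
    ("Hypertension map", 59.20, 0.069),
)

_EDVARDSSON = (
    ("Standard electrocardiogram", 6.50, 0.98),
    ("Echocardiography", 53.20, 0.86),
    ("Basic laboratory tests (with enzymes)", 65.87, 0.86),
    ("Ambulatory ECG monitoring", 43.70, 0.67),
    ("In-hospital ECG monitoring", 124.70, 0.55),
    ("Exercise testing", 32.10, 0.52),
    ("MRI or CT scan", 97.45, 0.47),
    ("Electroencephalography", 58.80, 0.39),
    ("Carotid sinus massage", 6.50, 0.36),
    ("TILT test", 124.10, 0.35),
    ("Electrophysiology testing", 2488.72, 0.25),
    ("Coronary angiography", 531.44, 0.23),
    ("External loop recording", 47.30, 0.12),
    ("Orthostatic blood pressure movements", 4.00, 0.48),
    ("Neurological or psychiatric evaluation", 30.90, 0.47),
)

_BARON_ESQUIVIAS = (
    ("Standard electrocardiogram", 6.50, 0.956),
    ("Echocardiography", 53.20, 0.021),
    ("Basic laboratory tests (without enzymes)", 53.87, 0.702),
    ("Enzymes", 34.40, 0.302),
    ("In-hospital ECG monitoring", 124.70, 0.171),
    ("Brain CT scan", 67.00, 0.09),
    ("Thorax CT scan", 74.70, 0.011),
    ("Chest X-ray", 9.00, 0.519),
    ("Carotid sinus massage", 6.50, 0.005),
    ("Orthostatic blood pressure movements", 4.00, 0.046),
)

_BRIGNOLE = (
    ("Standard electrocardiogram", 6.50, 1.00),
    ("Echocardiography", 53.20, 0.16),
    ("Abdominal echography", 20.12, 0.02),
    ("Basic laboratory tests (with enzymes)", 65.87, 0.35),
    ("In-hospital ECG monitoring", 124.70, 0.11),
    ("Exercise testing", 32.10, 0.03),
    ("MRI or CT scan", 97.45, 0.15),
    ("Chest X-ray", 9.00, 0.12),
    ("Electroencephalography", 58.80, 0.06),
    ("Carotid sinus massage", 6.50, 0.15),
    ("Carotid echo-doppler", 23.17, 0.04),
    ("TILT test", 124.10, 0.13),
    ("Electrophysiology testing", 2488.72, 0.03),
    ("Coronary angiography", 531.44, 0.02),
)

_FARWELL = (
    ("Echocardiography", 53.20, 0.1531),
    ("Ambulatory ECG monitoring", 43.70, 0.1122),
    ("External loop recorder (ELR)", 47.30, 0.2857),
    ("MRI", 127.90, 0.0102),
    ("Brain CT scan", 67.00, 0.0816),
    ("Electroencephalography", 58.80, 0.0204),
    ("Carotid echo-doppler", 23.17, 0.0510),
    ("Electrophysiology testing", 2488.72, 0.0102),
)

_SCENARIOS = {
    "Sousa Pedro": (_SOUSA_PEDRO, 164.32),
    "Edvardsson": (_EDVARDSSON, 1112.02),
    "Baron-Esquivias": (_BARON_ESQUIVIAS, 88.51),
    "Brignole": (_BRIGNOLE, 173.31),
    "Farwell": (_FARWELL, 72.41),
}


def base_clinical(horizon_years: float = 30.0) -> ClinicalParameters:
    """Base-case clinical parameters at the requested horizon (3 or 30 years)."""
    return ClinicalParameters(horizon_years=horizon_years)


def base_costs() -> CostParameters:
    """Base-case unit costs (canonical trauma cost 1,687.57 EUR per episode)."""
    return CostParameters()


def scenario_profiles() -> dict[str, ScenarioProfile]:
    """The five bundled workup scenarios, keyed by source-study name."""
    return {
        name: ScenarioProfile(name=name, items=items, printed_total=total)
        for name, (items, total) in _SCENARIOS.items()
    }


def default_life_table() -> LifeTable:
    """The bundled synthetic Gompertz-Makeham life table (see module docstring)."""
    from .synthetic import synthetic_life_table

    gm = GOMPERTZ_MAKEHAM_DEFAULTS
    return synthetic_life_table(gm["a"], gm["b"], gm["c"],
                                age_range=(gm["min_age"], gm["max_age"]))
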