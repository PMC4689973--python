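"""Packaged base-case inputs and synthetic fixtures.

Two kinds of values live here, kept apart by provenance flags:

* ``paper`` — quantities printed in the published base-case tables this
  model reimplements: treatment fracture relative risks, age-banded
  fracture incidence, utility multipliers, unit costs and drug prices
  (2013 USD), the population description (men aged 78, 23% prevalent
  vertebral fracture), discounting and the PSA draw count.
* ``placeholder`` — quantities the published analysis used but never
  printed, regenerated here with the statistical structure the analysis
  assumes: the US male life table (Gompertz–Makeham), the 6-month oral
  discontinuation schedule, post-fracture mortality relative risks, the
  age-specific baseline utilities, and the long-term-care admission
  fraction. The first two discontinuation probabilities are calibrated so
  that the hazard-ratio transform reproduces the published 73.6% one-year
  denosumab persistence; the life-table parameters are chosen once for
  plausible elderly-male mortality. Nothing is tuned to the published
  cost/QALY totals.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .config import (
    INJECTABLE_HR_ADJUSTED,
    ORAL_REFERENCE,
    SITES,
    ModelConfig,
    PersistenceSchedule,
    set_parameter,
)

PROVENANCE_PAPER = "paper"
PROVENANCE_PLACEHOLDER = "placeholder"

# -- published base-case parameters (provenance: paper) ----------------------

#: On-treatment fracture relative risks (hip, vertebral, NHNV) and yearly
#: drug acquisition costs; RR 1.00 encodes "no effect assumed at this site".
STRATEGY_DEFAULTS: list[dict] = [
    {
        "name": "generic_alendronate",
        "rr_hip": 0.62,
        "rr_vert": 0.62,
        "rr_nhnv": 0.82,
        "annual_drug_cost": 30.0,
        "admin_events": [],
        "max_treatment_years": 5.0,
        "offset_years": 2.0,
        "persistence_class": ORAL_REFERENCE,
    },
    {
        "name": "denosumab",
        "rr_hip": 0.38,
        "rr_vert": 0.36,
        "rr_nhnv": 0.84,
        "annual_drug_cost": 1650.0,
        "admin_events": [
            {"resource": "nurse_visit", "unit_cost": 42.0, "events_per_year": 2.0}
        ],
        "max_treatment_years": 5.0,
        "offset_years": 2.0,
        "persistence_class": INJECTABLE_HR_ADJUSTED,
        "hazard_ratio": 0.5,
    },
    {
        "name": "zoledronate",
        "rr_hip": 0.82,
        "rr_vert": 0.34,
        "rr_nhnv": 0.73,
        "annual_drug_cost": 1084.0,
        "admin_events": [
            {"resource": "iv_injection", "unit_cost": 151.0, "events_per_year": 1.0}
        ],
        "max_treatment_years": 5.0,
        "offset_years": 2.0,
        "persistence_class": INJECTABLE_HR_ADJUSTED,
        "hazard_ratio": 0.5,
    },
    {
        "name": "risedronate",
        "rr_hip": 0.85,
        "rr_vert": 0.56,
        "rr_nhnv": 0.80,
        "annual_drug_cost": 1708.0,
        "admin_events": [],
        "max_treatment_years": 5.0,
        "offset_years": 2.0,
        "persistence_class": ORAL_REFERENCE,
    },
    {
        "name": "ibandronate",
        "rr_hip": 1.00,
        "rr_vert": 0.51,
        "rr_nhnv": 1.00,
        "annual_drug_cost": 1332.0,
        "admin_events": [],
        "max_treatment_years": 5.0,
        "offset_years": 2.0,
        "persistence_class": ORAL_REFERENCE,
    },
    {
        "name": "teriparatide",
        "rr_hip": 0.25,
        "rr_vert": 0.35,
        "rr_nhnv": 0.47,
        "annual_drug_cost": 14514.0,
        "admin_events": [],
        "max_treatment_years": 2.0,  # licensed for 2 years only
        "offset_years": 2.0,
        "persistence_class": INJECTABLE_HR_ADJUSTED,
        "hazard_ratio": 0.5,
    },
]

#: Age-banded annual fracture incidence in untreated men.
INCIDENCE_BANDS: list[dict] = [
    {"lower": 75, "upper": 80, "rates": {"hip": 0.0053, "vertebral": 0.0045, "nhnv": 0.0076}},
    {"lower": 80, "upper": 85, "rates": {"hip": 0.0060, "vertebral": 0.0045, "nhnv": 0.0203}},
    {"lower": 85, "upper": None, "rates": {"hip": 0.0150, "vertebral": 0.0133, "nhnv": 0.0291}},
]

UTILITY_MULTIPLIERS = {
    "multiplier_year1": {"hip": 0.700, "vertebral": 0.590, "nhnv": 0.902},
    "multiplier_later": {"hip": 0.800, "vertebral": 0.930, "nhnv": 1.0},
}

COST_DEFAULTS = {
    "fracture_year1": {"hip": 28112.0, "vertebral": 7882.0, "nhnv": 9236.0},
    "hip_subsequent_annual": 9734.0,
    "ltc_daily": 236.0,
    # admission fraction after hip fracture: never printed; placeholder
    "ltc_admission_fraction": 0.20,
    "monitoring": [
        {"resource": "bmd_measurement", "unit_cost": 243.0, "events_per_year": 0.5},
        {"resource": "physician_visit", "unit_cost": 100.0, "events_per_year": 1.0},
    ],
}

POPULATION_DEFAULTS = {
    "start_age": 78,
    "max_age": 110,
    "prevalent_vertebral_fraction": 0.23,
    "cycle_length": 0.5,
}

RUN_DEFAULTS = {
    "annual_discount_rate_costs": 0.03,
    "annual_discount_rate_effects": 0.03,
    "psa_draws": 1000,
    "psa_seed": 2013,
    "wtp_threshold": 100000.0,
}

# -- placeholder generators --------------------------------------------------

#: Gompertz–Makeham parameters for the synthetic US male life table:
#: annual hazard h(a) = C + B * exp(G * a).
GOMPERTZ_MAKEHAM = {"C": 7e-4, "B": 3e-5, "G": 0.095}


def default_life_table(max_age: int = 110, min_age: int = 50) -> pd.DataFrame:
    """Synthetic male life table: age, annual death probability.

    Gompertz–Makeham mortality giving plausible elderly-male annual death
    probabilities (order 0.05 at 78), monotone in age, forced to 1 at
    ``max_age`` so the lifetime horizon closes.
    """
    if max_age > 120:
        raise ValueError("max_age must be <= 120")
    C, B, G = GOMPERTZ_MAKEHAM["C"], GOMPERTZ_MAKEHAM["B"], GOMPERTZ_MAKEHAM["G"]
    ages = list(range(min_age, max_age + 1))
    q = [1.0 - math.exp(-(C + B * math.exp(G * a))) for a in ages]
    q[-1] = 1.0
    return pd.DataFrame({"age": ages, "annual_death_probability": q})


def life_expectancy(life_table: pd.DataFrame, age: int) -> float:
    """Curtate-plus-half expected remaining years at ``age`` from a life table."""
    q = dict(zip(life_table["age"], life_table["annual_death_probability"]))
    surv, total = 1.0, 0.0
    a = age
    while a in q and surv > 1e-12:
        surv *= 1.0 - q[a]
        total += surv
        a += 1
    return total + 0.5


def default_persistence_schedule() -> PersistenceSchedule:
    """6-month oral-bisphosphonate discontinuation probabilities, cycles 1-6.

    The first two values are calibrated so that the hazard-ratio 0.5
    transform yields 73.6% one-year injectable persistence; the remaining
    four are placeholders with a declining discontinuation hazard.
    """
    return PersistenceSchedule(probabilities=[0.300, 0.226, 0.10, 0.08, 0.06, 0.05])


def default_mortality_rrs() -> dict[str, dict[str, float]]:
    """Placeholder post-fracture mortality relative risks.

    Structure as assumed by the analysis: hip and vertebral fractures raise
    mortality more in the first year than later; NHNV fractures raise it in
    the first year only.
    """
    return {
        "rr_first_year": {"hip": 3.0, "vertebral": 2.5, "nhnv": 1.4},
        "rr_subsequent": {"hip": 1.8, "vertebral": 1.5, "nhnv": 1.0},
    }


def default_baseline_utilities(max_age: int = 110, min_age: int = 50) -> pd.DataFrame:
    """Placeholder age-declining baseline utilities for men.

    Piecewise linear, anchored at 0.80 at age 78 and falling to 0.60 at
    age 110.
    """
    slope = (0.80 - 0.60) / (110 - 78)
    ages = list(range(min_age, max_age + 1))
    util = [min(1.0, 0.80 - slope * (a - 78)) for a in ages]
    return pd.DataFrame({"age": ages, "utility": util})


# -- assembly ----------------------------------------------------------------


def generate_config(seed: int = 0, overrides: dict[str, float] | None = None) -> ModelConfig:
    """The full default :class:`ModelConfig`, built in memory.

    Deterministic: the fixture generators contain no randomness, so any
    ``seed`` yields the identical configuration; the seed is recorded as
    the PSA seed. ``overrides`` are dotted parameter paths applied after
    assembly (still validated).
    """
    life = default_life_table(POPULATION_DEFAULTS["max_age"])
    util = default_baseline_utilities(POPULATION_DEFAULTS["max_age"])
    cfg = ModelConfig(
        population=POPULATION_DEFAULTS,
        strategies=STRATEGY_DEFAULTS,
        epidemiology={"bands": INCIDENCE_BANDS},
        mortality={
            "life_table": dict(zip(life["age"], life["annual_death_probability"])),
            **default_mortality_rrs(),
        },
        utilities={
            "baseline_by_age": dict(zip(util["age"], util["utility"])),
            **UTILITY_MULTIPLIERS,
        },
        costs=COST_DEFAULTS,
        persistence_schedule=default_persistence_schedule(),
        run_settings={**RUN_DEFAULTS, "psa_seed": int(seed)},
    )
    for path, value in (overrides or {}).items():
        set_parameter(cfg, path, value)
    return cfg


def _prepend_comment(path: Path, comment: str) -> None:
    path.write_text(f"# {comment}\n" + path.read_text())


def write_fixtures(outdir: str | Path, seed: int = 0) -> Path:
    """Write the default YAML config and its CSV fixtures to ``outdir``.

    Each CSV carries a provenance header comment (``paper`` for
    printed-table values, ``placeholder`` for regenerated inputs).
    Deterministic given ``seed``; returns the YAML path.
    """
    from .config import save_config  # local import to avoid cycle at module load

    outdir = Path(outdir)
    cfg = generate_config(seed)
    yaml_path = save_config(cfg, outdir, yaml_name="default.yaml")
    provenance = {
        "life_table.csv": PROVENANCE_PLACEHOLDER,
        "persistence.csv": PROVENANCE_PLACEHOLDER,
        "mortality_rr.csv": PROVENANCE_PLACEHOLDER,
        "baseline_utility.csv": PROVENANCE_PLACEHOLDER,
        "incidence.csv": PROVENANCE_PAPER,
    }
    for fname, prov in provenance.items():
        _prepend_comment(outdir / fname, f"provenance: {prov}")
    return yaml_path


def load_reference_results() -> pd.DataFrame:
    """Published base-case totals (cost, LYs, QALYs) per strategy.

    These are the printed headline results of the original analysis,
    shipped as data so the frontier arithmetic can be checked against them;
    they are outputs of the original model, never inputs to this one.
    """
    path = Path(__file__).parent / "data" / "reference_results.csv"
    return pd.read_csv(path, comment="#", float_precision="round_trip")
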