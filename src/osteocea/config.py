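"""Model parameters: typed schema, validation, file loading, and age lookups.

Every quantity the cohort model consumes lives in a :class:`ModelConfig`:
the simulated population, the treatment strategies with their site-specific
fracture relative risks and costs, background fracture incidence, mortality
(a male life table plus post-fracture relative risks), health-state
utilities, resource costs, the oral-bisphosphonate persistence schedule, and
run settings (discount rates, willingness-to-pay, PSA draws).

Configurations are stored as one YAML file referencing CSV tables (life
table, fracture incidence, persistence schedule, post-fracture mortality
relative risks, age-specific baseline utilities), so real registry or
life-table data can replace the packaged fixtures without code changes.
All monetary values are 2013 USD; all rates are annual unless a field name
says otherwise.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Fracture sites, in the fixed order used by the engine's event arrays.
SITES: tuple[str, ...] = ("hip", "vertebral", "nhnv")

Site = Literal["hip", "vertebral", "nhnv"]

ORAL_REFERENCE = "oral_reference"
INJECTABLE_HR_ADJUSTED = "injectable_hr_adjusted"


class ConfigError(ValueError):
    """Raised for configuration problems outside pydantic's field validation."""


class _Model(BaseModel):
    model_config = ConfigDict(validate_assignment=True, extra="forbid")


def _require_all_sites(d: dict) -> dict:
    if set(d) != set(SITES):
        raise ValueError(f"expected exactly the keys {SITES}, got {sorted(d)}")
    return d


class Population(_Model):
    """Cohort entering the model: elderly men, 23% with a prevalent vertebral fracture."""

    start_age: int = Field(ge=40, lt=120)
    max_age: int = Field(le=120)
    prevalent_vertebral_fraction: float = Field(ge=0.0, le=1.0)
    cycle_length: float = 0.5  # years; the model is built on 6-month cycles

    @field_validator("cycle_length")
    @classmethod
    def _half_year_cycles(cls, v: float) -> float:
        if v != 0.5:
            raise ValueError("cycle_length is fixed at 0.5 years (6-month cycles)")
        return v

    @model_validator(mode="after")
    def _age_order(self) -> "Population":
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")
        return self

    @property
    def n_cycles(self) -> int:
        """Number of 6-month cycles from start_age to max_age (lifetime horizon)."""
        return int(round((self.max_age - self.start_age) / self.cycle_length))


class AdminEvent(_Model):
    """A recurring administration or monitoring resource while on treatment."""

    resource: str
    unit_cost: float = Field(ge=0.0)
    events_per_year: float = Field(ge=0.0)


class Strategy(_Model):
    """One treatment arm: efficacy, costs, duration, persistence class, offset rule.

    ``rr_hip``/``rr_vert``/``rr_nhnv`` are on-treatment fracture relative
    risks versus no treatment; an RR of exactly 1.0 encodes "no effect
    assumed at this site" (and is a real value, not a missing one).
    ``hazard_ratio`` is the discontinuation hazard ratio versus the oral
    reference schedule and is used only by the ``injectable_hr_adjusted``
    persistence class.
    """

    name: str
    rr_hip: float = Field(gt=0.0)
    rr_vert: float = Field(gt=0.0)
    rr_nhnv: float = Field(gt=0.0)
    annual_drug_cost: float = Field(ge=0.0)
    admin_events: list[AdminEvent] = Field(default_factory=list)
    max_treatment_years: float = Field(gt=0.0)
    offset_years: float = Field(ge=0.0)
    persistence_class: Literal["oral_reference", "injectable_hr_adjusted"]
    hazard_ratio: float = Field(default=1.0, gt=0.0)

    def rr(self, site: Site) -> float:
        return {"hip": self.rr_hip, "vertebral": self.rr_vert, "nhnv": self.rr_nhnv}[site]

    @property
    def max_treatment_cycles(self) -> int:
        return int(round(self.max_treatment_years / 0.5))


class AgeBand(_Model):
    """Closed-open age band [lower, upper) with annual incidence per site.

    ``upper`` of ``None`` marks the open-ended terminal band (e.g. 85+).
    """

    lower: int
    upper: Optional[int] = None
    rates: dict[Site, float]

    @field_validator("rates")
    @classmethod
    def _rates_ok(cls, v: dict) -> dict:
        _require_all_sites(v)
        for site, p in v.items():
            if not (0.0 <= p < 1.0):
                raise ValueError(f"annual incidence for {site} must be in [0, 1), got {p}")
        return v

    def contains(self, age: float) -> bool:
        return age >= self.lower and (self.upper is None or age < self.upper)


class FractureEpidemiology(_Model):
    """Age-banded annual incidence of hip, clinical vertebral and NHNV fracture."""

    bands: list[AgeBand] = Field(min_length=1)

    @model_validator(mode="after")
    def _contiguous_open_ended(self) -> "FractureEpidemiology":
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if prev.upper is None:
                raise ValueError("bands: only the last band may be open-ended")
            if prev.upper != nxt.lower:
                raise ValueError(
                    f"bands: not contiguous at age {prev.upper} vs {nxt.lower}"
                )
        if self.bands[-1].upper is not None:
            raise ValueError("bands: the last band must be open-ended (upper = null)")
        return self

    def incidence_for_age(self, age: float, site: Site) -> float:
        """Annual fracture probability for the band containing ``age``."""
        return incidence_for_age(self, age, site)


def incidence_for_age(epi: FractureEpidemiology, age: float, site: Site) -> float:
    """Look up the annual fracture incidence for ``age`` and ``site``.

    Ages beyond the last band use the open-ended terminal band; ages below
    the first band are an error.
    """
    if age < epi.bands[0].lower:
        raise ConfigError(
            f"age {age} is below the first incidence band (lower {epi.bands[0].lower})"
        )
    for band in epi.bands:
        if band.contains(age):
            return band.rates[site]
    raise AssertionError("unreachable: terminal band is open-ended")


class MortalityInputs(_Model):
    """US male life table plus post-fracture mortality relative risks.

    The first year after a hip or vertebral fracture carries a higher
    mortality RR than subsequent years; NHNV fractures raise mortality in
    the first year only (subsequent RR fixed at 1).
    """

    life_table: dict[int, float]
    rr_first_year: dict[Site, float]
    rr_subsequent: dict[Site, float]

    @field_validator("life_table")
    @classmethod
    def _probs(cls, v: dict) -> dict:
        if not v:
            raise ValueError("life_table must not be empty")
        for age, q in v.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"life_table: q({age}) = {q} outside [0, 1]")
        return v

    @field_validator("rr_first_year", "rr_subsequent")
    @classmethod
    def _rr_ok(cls, v: dict) -> dict:
        _require_all_sites(v)
        for site, rr in v.items():
            if rr < 1.0:
                raise ValueError(f"mortality RR for {site} must be >= 1, got {rr}")
        return v

    @model_validator(mode="after")
    def _nhnv_first_year_only(self) -> "MortalityInputs":
        if self.rr_subsequent["nhnv"] != 1.0:
            raise ValueError("rr_subsequent[nhnv] must be exactly 1 (first-year effect only)")
        return self

    def annual_death_probability(self, age: float) -> float:
        """Annual background death probability at integer ``floor(age)``, clamped to the table range."""
        a = int(age)
        ages = self.life_table
        a = min(max(a, min(ages)), max(ages))
        return ages[a]


class UtilityInputs(_Model):
    """Baseline age-specific utilities and fracture-state multipliers."""

    baseline_by_age: dict[int, float]
    multiplier_year1: dict[Site, float]
    multiplier_later: dict[Site, float]

    @field_validator("baseline_by_age")
    @classmethod
    def _baseline_ok(cls, v: dict) -> dict:
        if not v:
            raise ValueError("baseline_by_age must not be empty")
        for age, u in v.items():
            if not (0.0 < u <= 1.0):
                raise ValueError(f"baseline utility at age {age} must be in (0, 1], got {u}")
        return v

    @field_validator("multiplier_year1", "multiplier_later")
    @classmethod
    def _mult_ok(cls, v: dict) -> dict:
        _require_all_sites(v)
        for site, m in v.items():
            if not (0.0 < m <= 1.0):
                raise ValueError(f"utility multiplier for {site} must be in (0, 1], got {m}")
        return v

    @model_validator(mode="after")
    def _nhnv_first_year_only(self) -> "UtilityInputs":
        if self.multiplier_later["nhnv"] != 1.0:
            raise ValueError("multiplier_later[nhnv] must be exactly 1 (first-year effect only)")
        return self

    def baseline(self, age: float) -> float:
        a = int(age)
        a = min(max(a, min(self.baseline_by_age)), max(self.baseline_by_age))
        return self.baseline_by_age[a]


class CostInputs(_Model):
    """Fracture treatment, long-term care, and monitoring unit costs (2013 USD)."""

    fracture_year1: dict[Site, float]
    hip_subsequent_annual: float = Field(ge=0.0)
    ltc_daily: float = Field(ge=0.0)
    ltc_admission_fraction: float = Field(ge=0.0, le=1.0)
    monitoring: list[AdminEvent] = Field(default_factory=list)

    @field_validator("fracture_year1")
    @classmethod
    def _cost_ok(cls, v: dict) -> dict:
        _require_all_sites(v)
        for site, c in v.items():
            if c < 0:
                raise ValueError(f"fracture_year1[{site}] must be >= 0, got {c}")
        return v


class RunSettings(_Model):
    annual_discount_rate_costs: float = Field(ge=0.0)
    annual_discount_rate_effects: float = Field(ge=0.0)
    psa_draws: int = Field(ge=1)
    psa_seed: int = 0
    wtp_threshold: float = Field(ge=0.0)


class PersistenceSchedule(_Model):
    """6-month discontinuation probabilities for treatment cycles 1-6 (years 0-3).

    These are the oral-bisphosphonate reference probabilities; injectable
    strategies transform them through their discontinuation hazard ratio.
    Beyond cycle 6 no further premature discontinuation occurs: patients
    still on therapy continue until planned termination.
    """

    probabilities: list[float] = Field(min_length=6, max_length=6)

    @field_validator("probabilities")
    @classmethod
    def _probs_ok(cls, v: list[float]) -> list[float]:
        for i, p in enumerate(v, start=1):
            if not (0.0 <= p < 1.0):
                raise ValueError(f"discontinuation probability for cycle {i} must be in [0, 1), got {p}")
        return v

    def probability(self, cycle: int) -> float:
        """Oral-reference discontinuation probability at treatment cycle ``cycle`` (1-based)."""
        if cycle < 1:
            raise ConfigError(f"cycle must be >= 1, got {cycle}")
        return self.probabilities[cycle - 1] if cycle <= len(self.probabilities) else 0.0


class ModelConfig(_Model):
    """Complete, validated parameter set for one model run."""

    population: Population
    strategies: list[Strategy] = Field(min_length=2)
    epidemiology: FractureEpidemiology
    mortality: MortalityInputs
    utilities: UtilityInputs
    costs: CostInputs
    persistence_schedule: PersistenceSchedule
    run_settings: RunSettings

    @model_validator(mode="after")
    def _cross_checks(self) -> "ModelConfig":
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"strategies: duplicate names in {names}")
        if self.population.start_age < self.epidemiology.bands[0].lower:
            raise ValueError(
                "population.start_age is below the first incidence band"
            )
        q_max = self.mortality.life_table.get(self.population.max_age)
        if q_max != 1.0:
            raise ValueError(
                f"mortality.life_table must force q = 1 at max_age {self.population.max_age}"
            )
        return self

    # -- convenience lookups -------------------------------------------------

    @property
    def n_cycles(self) -> int:
        return self.population.n_cycles

    def age_at_cycle_start(self, cycle: int) -> float:
        """Cohort age at the start of 1-based cycle ``cycle``."""
        return self.population.start_age + 0.5 * (cycle - 1)

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise ConfigError(f"no strategy named {name!r}")


# ---------------------------------------------------------------------------
# File I/O: one YAML document referencing CSV tables.
# ---------------------------------------------------------------------------

_TABLE_KEYS = ("life_table", "incidence", "persistence", "mortality_rr", "baseline_utility")


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise ConfigError(f"referenced table file not found: {path}")
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a :class:`ModelConfig` from a YAML file.

    CSV tables referenced in the YAML's ``tables`` section are resolved
    relative to the YAML file's directory. Validation failures raise a
    :class:`pydantic.ValidationError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a YAML mapping")
    try:
        tables = raw.pop("tables")
    except KeyError:
        raise ConfigError("config is missing the 'tables' section") from None
    missing = [k for k in _TABLE_KEYS if k not in tables]
    if missing:
        raise ConfigError(f"tables section is missing {missing}")
    base = path.parent

    life = _read_csv(base / tables["life_table"])
    life_table = {int(a): float(q) for a, q in zip(life["age"], life["annual_death_probability"])}

    inc = _read_csv(base / tables["incidence"])
    bands = []
    for _, row in inc.iterrows():
        upper = None if pd.isna(row["age_upper"]) else int(row["age_upper"])
        bands.append(
            {
                "lower": int(row["age_lower"]),
                "upper": upper,
                "rates": {s: float(row[s]) for s in SITES},
            }
        )

    pers = _read_csv(base / tables["persistence"]).sort_values("cycle")
    schedule = {"probabilities": [float(p) for p in pers["discontinuation_probability"]]}

    mrr = _read_csv(base / tables["mortality_rr"]).set_index("site")
    mortality = {
        "life_table": life_table,
        "rr_first_year": {s: float(mrr.loc[s, "rr_first_year"]) for s in SITES},
        "rr_subsequent": {s: float(mrr.loc[s, "rr_subsequent"]) for s in SITES},
    }

    util = _read_csv(base / tables["baseline_utility"])
    utilities = dict(raw.pop("utilities", {}))
    utilities["baseline_by_age"] = {int(a): float(u) for a, u in zip(util["age"], util["utility"])}

    return ModelConfig(
        epidemiology={"bands": bands},
        mortality=mortality,
        utilities=utilities,
        persistence_schedule=schedule,
        **raw,
    )


def save_config(config: ModelConfig, outdir: str | Path, yaml_name: str = "config.yaml") -> Path:
    """Write ``config`` as a YAML file plus CSV tables; returns the YAML path.

    ``load_config(save_config(cfg, d))`` reproduces an identical parameter set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {
            "age": list(config.mortality.life_table),
            "annual_death_probability": list(config.mortality.life_table.values()),
        }
    ).to_csv(outdir / "life_table.csv", index=False)

    inc_rows = [
        {"age_lower": b.lower, "age_upper": b.upper, **{s: b.rates[s] for s in SITES}}
        for b in config.epidemiology.bands
    ]
    pd.DataFrame(inc_rows).to_csv(outdir / "incidence.csv", index=False)

    pd.DataFrame(
        {
            "cycle": range(1, 7),
            "discontinuation_probability": config.persistence_schedule.probabilities,
        }
    ).to_csv(outdir / "persistence.csv", index=False)

    pd.DataFrame(
        {
            "site": list(SITES),
            "rr_first_year": [config.mortality.rr_first_year[s] for s in SITES],
            "rr_subsequent": [config.mortality.rr_subsequent[s] for s in SITES],
        }
    ).to_csv(outdir / "mortality_rr.csv", index=False)

    pd.DataFrame(
        {
            "age": list(config.utilities.baseline_by_age),
            "utility": list(config.utilities.baseline_by_age.values()),
        }
    ).to_csv(outdir / "baseline_utility.csv", index=False)

    doc = {
        "population": config.population.model_dump(),
        "run_settings": config.run_settings.model_dump(),
        "utilities": {
            "multiplier_year1": config.utilities.multiplier_year1,
            "multiplier_later": config.utilities.multiplier_later,
        },
        "costs": config.costs.model_dump(),
        "strategies": [s.model_dump() for s in config.strategies],
        "tables": {
            "life_table": "life_table.csv",
            "incidence": "incidence.csv",
            "persistence": "persistence.csv",
            "mortality_rr": "mortality_rr.csv",
            "baseline_utility": "baseline_utility.csv",
        },
    }
    yaml_path = outdir / yaml_name
    yaml_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return yaml_path


def default_config() -> ModelConfig:
    """The packaged base-case configuration (printed-table values + fixtures)."""
    return load_config(Path(__file__).parent / "data" / "default.yaml")


# ---------------------------------------------------------------------------
# Dotted parameter paths (used by the sensitivity analyses).
# ---------------------------------------------------------------------------


def _resolve(config: ModelConfig, path: str):
    """Walk a dotted path; returns (parent, final key/attr, kind)."""
    tokens = path.split(".")
    obj = config
    for i, tok in enumerate(tokens):
        last = i == len(tokens) - 1
        if isinstance(obj, BaseModel):
            if tok not in type(obj).model_fields:
                raise ConfigError(f"unknown parameter path {path!r}: no field {tok!r}")
            if last:
                return obj, tok, "attr"
            obj = getattr(obj, tok)
        elif isinstance(obj, list):
            # lists of named models (strategies, admin events) are indexed by name
            matches = [x for x in obj if getattr(x, "name", getattr(x, "resource", None)) == tok]
            if not matches:
                raise ConfigError(f"unknown parameter path {path!r}: no element {tok!r}")
            if last:
                raise ConfigError(f"parameter path {path!r} ends on a list element")
            obj = matches[0]
        elif isinstance(obj, dict):
            key: object = tok
            if key not in obj:
                try:
                    key = int(tok)
                except ValueError:
                    pass
            if key not in obj:
                raise ConfigError(f"unknown parameter path {path!r}: no key {tok!r}")
            if last:
                return obj, key, "item"
            obj = obj[key]
        else:
            raise ConfigError(f"parameter path {path!r} descends into a scalar at {tok!r}")
    raise AssertionError("unreachable")


def get_parameter(config: ModelConfig, path: str) -> float:
    """Read a scalar parameter by dotted path, e.g. ``strategies.denosumab.rr_hip``."""
    parent, key, kind = _resolve(config, path)
    return getattr(parent, key) if kind == "attr" else parent[key]


def set_parameter(config: ModelConfig, path: str, value: float) -> None:
    """Set a scalar parameter in place; pydantic re-validates attribute assignments."""
    parent, key, kind = _resolve(config, path)
    if kind == "attr":
        setattr(parent, key, value)
    else:
        parent[key] = value


def with_parameters(config: ModelConfig, overrides: dict[str, float]) -> ModelConfig:
    """A deep copy of ``config`` with dotted-path ``overrides`` applied."""
    new = config.model_copy(deep=True)
    for path, value in overrides.items():
        set_parameter(new, path, value)
    return new
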