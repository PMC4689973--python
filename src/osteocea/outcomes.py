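"""Discounted lifetime costs, QALYs, LYs, and 10-year fracture risks.

Accounting conventions:

* Discounting is annual (3% base case) applied at ``(1 + r) ** (-0.5 c)``
  for cycle ``c``; no half-cycle correction in the base case.
* Occupancy "during" a cycle is the end-of-cycle distribution.
* First-year fracture costs attach once to the incident event, so the
  two-cycle tunnel cannot double-count them. Hip fractures additionally
  carry a recurring annual cost while in the post-hip state; vertebral and
  NHNV fractures carry no costs beyond the first year.
* A fixed fraction of incident hip fractures is admitted to long-term care
  permanently; the LTC pool is costed per day (182.625 days per cycle) and
  shrinks with post-hip mortality.
* Drug, administration and monitoring costs accrue only while the
  subcohort is on treatment (and alive); fracture and LTC costs continue
  after discontinuation.
* QALYs weight end-of-cycle occupancy by age-specific baseline utility
  times the health-state multiplier; LYs use weight 1.
* 10-year fracture risks are undiscounted cumulative incident-event
  fractions over cycles 1-20 (refractures included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SITES, ModelConfig, Strategy
from .markov import DEAD, STATE_INDEX, CohortTrace
from .treatment import SubcohortProfile

DAYS_PER_CYCLE = 182.625  # 365.25 / 2, consistent with annual rates

#: Cost components reported in the disaggregated cost table.
COST_COMPONENTS = (
    "drug",
    "admin_monitoring",
    "fracture_year1",
    "fracture_subsequent",
    "long_term_care",
)

#: (state, multiplier key) pairs: which utility multiplier each live state uses.
_STATE_UTILITY: dict[str, tuple[str, str] | None] = {
    "well": None,
    "hip_y1a": ("hip", "year1"),
    "hip_y1b": ("hip", "year1"),
    "post_hip": ("hip", "later"),
    "vert_y1a": ("vertebral", "year1"),
    "vert_y1b": ("vertebral", "year1"),
    "post_vert": ("vertebral", "later"),
    "nhnv_y1a": ("nhnv", "year1"),
    "nhnv_y1b": ("nhnv", "year1"),
    "post_nhnv": ("nhnv", "later"),  # validated to 1: no effect beyond year 1
}


@dataclass
class StrategyTotals:
    """Discounted lifetime totals for one strategy."""

    name: str
    cost: float
    qalys: float
    lys: float
    components: dict[str, float] = field(default_factory=dict)
    ten_year_risk: dict[str, float] = field(default_factory=dict)


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount factor for the end of 1-based cycle ``cycle``."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    return float((1.0 + annual_rate) ** (-0.5 * cycle))


def ltc_occupancy(trace: CohortTrace, config: ModelConfig) -> np.ndarray:
    """Long-term-care pool per cycle (fraction of the initial cohort).

    The pool is fed by ``ltc_admission_fraction`` of each cycle's incident
    hip fractures and persists until death, decaying with the post-hip
    (subsequent-year) mortality.
    """
    frac = config.costs.ltc_admission_fraction
    rr = config.mortality.rr_subsequent["hip"]
    hip_k = SITES.index("hip")
    pool = np.zeros(trace.n_cycles + 1)
    for c in range(1, trace.n_cycles + 1):
        q = config.mortality.annual_death_probability(config.age_at_cycle_start(c))
        p_death = 1.0 if q >= 1.0 else 1.0 - (1.0 - q) ** 0.5
        surv = max(0.0, 1.0 - min(1.0, p_death * rr))
        pool[c] = pool[c - 1] * surv + frac * trace.events[c - 1, hip_k]
    return pool


def cycle_costs(
    trace: CohortTrace,
    strategy: Strategy,
    subcohort: SubcohortProfile,
    config: ModelConfig,
    cycle: int,
    ltc_pool: np.ndarray | None = None,
) -> dict[str, float]:
    """Undiscounted cost components accrued during 1-based ``cycle``."""
    costs = config.costs
    occ = trace.occupancy[cycle]
    alive = trace.alive(cycle)
    out = dict.fromkeys(COST_COMPONENTS, 0.0)

    if subcohort.on_treatment(cycle):
        out["drug"] = strategy.annual_drug_cost * 0.5 * alive
        per_year = sum(
            ev.unit_cost * ev.events_per_year
            for ev in (*strategy.admin_events, *costs.monitoring)
        )
        out["admin_monitoring"] = per_year * 0.5 * alive

    out["fracture_year1"] = sum(
        trace.events[cycle - 1, k] * costs.fracture_year1[site]
        for k, site in enumerate(SITES)
    )
    out["fracture_subsequent"] = (
        costs.hip_subsequent_annual * 0.5 * occ[STATE_INDEX["post_hip"]]
    )
    pool = ltc_occupancy(trace, config) if ltc_pool is None else ltc_pool
    out["long_term_care"] = costs.ltc_daily * DAYS_PER_CYCLE * pool[cycle]
    return out


def cycle_qalys(trace: CohortTrace, config: ModelConfig, cycle: int) -> float:
    """Undiscounted QALYs accrued during 1-based ``cycle``."""
    util = config.utilities
    age = config.age_at_cycle_start(cycle)
    base = util.baseline(age)
    occ = trace.occupancy[cycle]
    total = 0.0
    for state, key in _STATE_UTILITY.items():
        if key is None:
            mult = 1.0
        else:
            site, period = key
            mult = (util.multiplier_year1 if period == "year1" else util.multiplier_later)[site]
        total += occ[STATE_INDEX[state]] * base * mult
    return 0.5 * total


def accumulate(
    subcohort_traces: list[tuple[SubcohortProfile, CohortTrace]],
    strategy: Strategy,
    config: ModelConfig,
) -> StrategyTotals:
    """Weight-averaged, discounted lifetime totals over all subcohorts."""
    rs = config.run_settings
    n = config.n_cycles
    components = dict.fromkeys(COST_COMPONENTS, 0.0)
    qalys = 0.0
    lys = 0.0
    events10 = dict.fromkeys(SITES, 0.0)
    ten_year_cycles = min(n, 20)

    for sub, trace in subcohort_traces:
        w = sub.weight
        if w == 0.0:
            continue
        pool = ltc_occupancy(trace, config)
        for c in range(1, n + 1):
            dfc = discount_factor(c, rs.annual_discount_rate_costs)
            dfe = discount_factor(c, rs.annual_discount_rate_effects)
            for comp, value in cycle_costs(trace, strategy, sub, config, c, pool).items():
                components[comp] += w * dfc * value
            qalys += w * dfe * cycle_qalys(trace, config, c)
            lys += w * dfe * 0.5 * trace.alive(c)
        for site in SITES:
            events10[site] += w * trace.cumulative_events(site, ten_year_cycles)

    return StrategyTotals(
        name=strategy.name,
        cost=sum(components.values()),
        qalys=qalys,
        lys=lys,
        components=components,
        ten_year_risk=events10,
    )
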