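"""Treatment persistence, discontinuation subcohorts, and effective efficacy.

Premature discontinuation can occur at the start of each of the first six
6-month cycles (three years); patients still on therapy after three years
continue until planned termination (five years, or two for teriparatide).
Oral strategies use the registry-derived discontinuation schedule directly;
injectable strategies (denosumab, teriparatide, zoledronate) transform each
6-month probability through the denosumab-vs-alendronate discontinuation
hazard ratio of 0.5 via the proportional-hazards identity
``p' = 1 - (1 - p) ** HR``.

Because discontinuation is independent of health state, each strategy's
cohort decomposes exactly into subcohorts by discontinuation time, with
weights fixed at baseline; each subcohort is simulated with its own
per-cycle effective relative-risk profile and the traces are weight-
averaged afterwards.

After stopping, anti-fracture efficacy does not vanish instantly: the
relative risk decays linearly from the on-treatment value to 1.0 over the
offset time, which is capped by the time actually spent on treatment
(rounded up to whole years; first-cycle dropouts get no offset at all).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import (
    INJECTABLE_HR_ADJUSTED,
    PersistenceSchedule,
    Site,
    Strategy,
)


@dataclass(frozen=True)
class SubcohortProfile:
    """One discontinuation-time slice of a strategy's cohort.

    ``stop_cycle`` is the last cycle spent on treatment (0 = never treated,
    i.e. discontinuation at the very start of cycle 1). ``offset_years`` is
    the offset duration this subcohort actually receives.
    """

    label: str
    stop_cycle: int
    weight: float
    offset_years: float

    def on_treatment(self, cycle: int) -> bool:
        return 1 <= cycle <= self.stop_cycle

    @property
    def years_on_treatment(self) -> float:
        return 0.5 * self.stop_cycle


def discontinuation_probability(
    strategy: Strategy, schedule: PersistenceSchedule, cycle: int
) -> float:
    """6-month discontinuation probability for ``strategy`` at treatment ``cycle``.

    Zero beyond cycle 6 (year 3): remaining patients persist to planned
    termination. Injectable strategies apply the proportional-hazards
    transform with their discontinuation hazard ratio.
    """
    p = schedule.probability(cycle)
    if strategy.persistence_class == INJECTABLE_HR_ADJUSTED and strategy.hazard_ratio != 1.0:
        return 1.0 - (1.0 - p) ** strategy.hazard_ratio
    return p


def _applicable_offset(strategy: Strategy, stop_cycle: int, planned: bool) -> float:
    """Offset duration given time on treatment; cannot exceed treatment duration.

    Premature discontinuers get ``min(offset, ceil(years on treatment))``
    (stopping "by year 1" earns a 1-year offset); dropouts in the first
    cycle, who never took the drug for a full cycle, get none. Completers
    get ``min(offset, planned treatment duration)``.
    """
    if stop_cycle <= 0:
        return 0.0
    if planned:
        return min(strategy.offset_years, strategy.max_treatment_years)
    return min(strategy.offset_years, float(math.ceil(0.5 * stop_cycle)))


def build_subcohorts(
    strategy: Strategy, schedule: PersistenceSchedule
) -> list[SubcohortProfile]:
    """Partition the cohort by discontinuation time.

    One subcohort per possible discontinuation cycle (1-6) plus the
    completer subcohort; weights are the exact probabilities of stopping at
    that cycle (sequential products of persistence), so they sum to 1.
    """
    subs: list[SubcohortProfile] = []
    surviving = 1.0
    n_risk = len(schedule.probabilities)
    for k in range(1, n_risk + 1):
        p = discontinuation_probability(strategy, schedule, k)
        weight = surviving * p
        stop = min(k - 1, strategy.max_treatment_cycles)
        planned = stop == strategy.max_treatment_cycles
        subs.append(
            SubcohortProfile(
                label=f"discontinue_cycle_{k}",
                stop_cycle=stop,
                weight=weight,
                offset_years=_applicable_offset(strategy, stop, planned),
            )
        )
        surviving *= 1.0 - p
    stop = strategy.max_treatment_cycles
    subs.append(
        SubcohortProfile(
            label="completer",
            stop_cycle=stop,
            weight=surviving,
            offset_years=_applicable_offset(strategy, stop, planned=True),
        )
    )
    return subs


def offset_rr(rr: float, time_since_stop: float, offset_years: float) -> float:
    """Residual relative risk ``time_since_stop`` years after stopping treatment.

    Linear decay from the on-treatment ``rr`` to 1.0 over ``offset_years``;
    1.0 immediately when no offset applies.
    """
    if offset_years <= 0.0:
        return 1.0
    frac = min(1.0, max(0.0, time_since_stop) / offset_years)
    return rr + (1.0 - rr) * frac


def effective_rr(
    strategy: Strategy, subcohort: SubcohortProfile, cycle: int, site: Site
) -> float:
    """Effective fracture relative risk for this subcohort during ``cycle``.

    On treatment the trial relative risk applies; off treatment the offset
    decay is evaluated at the cycle's midpoint.
    """
    if subcohort.on_treatment(cycle):
        return strategy.rr(site)
    cycles_off = cycle - subcohort.stop_cycle
    midpoint = (cycles_off - 0.5) * 0.5
    return offset_rr(strategy.rr(site), midpoint, subcohort.offset_years)


def one_year_persistence(strategy: Strategy, schedule: PersistenceSchedule) -> float:
    """Fraction still on treatment after one year (two cycles)."""
    out = 1.0
    for cycle in (1, 2):
        out *= 1.0 - discontinuation_probability(strategy, schedule, cycle)
    return out
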