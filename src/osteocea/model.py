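"""Orchestration: run strategies end-to-end from a :class:`ModelConfig`.

Ties the pieces together in the order the method runs: build the
discontinuation subcohorts for each strategy, simulate each subcohort's
cohort trace with its per-cycle effective relative risks, accumulate
discounted totals, and (optionally) rank the strategies on the
cost-effectiveness frontier.
"""

from __future__ import annotations

import math

import numpy as np

from .config import SITES, ModelConfig, Strategy
from .frontier import CEATable, frontier
from .markov import (
    N_STATES,
    STATE_INDEX,
    CohortTrace,
    TransitionMatrix,
    run_cohort,
    transition_matrix,
)
from .outcomes import StrategyTotals, accumulate
from .treatment import SubcohortProfile, build_subcohorts, effective_rr


def initial_distribution(config: ModelConfig) -> np.ndarray:
    """Initial cohort: prevalent vertebral fractures start post-vertebral, rest well."""
    dist = np.zeros(N_STATES)
    pv = config.population.prevalent_vertebral_fraction
    dist[STATE_INDEX["post_vert"]] = pv
    dist[STATE_INDEX["well"]] = 1.0 - pv
    return dist


def strategy_traces(
    config: ModelConfig, strategy: Strategy, _cache: dict | None = None
) -> list[tuple[SubcohortProfile, CohortTrace]]:
    """Simulate every discontinuation subcohort of ``strategy``.

    Transition matrices are memoised on (integer age, effective RRs): once
    a subcohort's offset has fully waned its matrices coincide with the
    untreated ones, which keeps repeated runs cheap.
    """
    cache: dict = {} if _cache is None else _cache
    init = initial_distribution(config)
    out = []
    for sub in build_subcohorts(strategy, config.persistence_schedule):
        def provider(cycle: int, _sub=sub) -> TransitionMatrix:
            age = config.age_at_cycle_start(cycle)
            rr = tuple(effective_rr(strategy, _sub, cycle, site) for site in SITES)
            key = (math.floor(age), rr)
            if key not in cache:
                cache[key] = transition_matrix(
                    cycle, age, dict(zip(SITES, rr)), config
                )
            return cache[key]

        trace = run_cohort(
            init, provider, config.n_cycles, start_age=config.population.start_age
        )
        out.append((sub, trace))
    return out


def aggregate_trace(
    subcohort_traces: list[tuple[SubcohortProfile, CohortTrace]]
) -> CohortTrace:
    """Weight-average the subcohort traces into one strategy-level trace."""
    occ = sum(s.weight * t.occupancy for s, t in subcohort_traces)
    ev = sum(s.weight * t.events for s, t in subcohort_traces)
    return CohortTrace(
        occupancy=occ, events=ev, start_age=subcohort_traces[0][1].start_age
    )


def run_strategy(config: ModelConfig, strategy: Strategy) -> StrategyTotals:
    """Discounted lifetime totals for one strategy under ``config``."""
    return accumulate(strategy_traces(config, strategy), strategy, config)


def run_all(config: ModelConfig) -> list[StrategyTotals]:
    """Totals for every configured strategy (transition matrices shared)."""
    cache: dict = {}
    return [
        accumulate(strategy_traces(config, s, cache), s, config)
        for s in config.strategies
    ]


def run_cea(config: ModelConfig) -> CEATable:
    """Full base-case analysis: run all strategies and rank them."""
    return frontier(run_all(config))
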