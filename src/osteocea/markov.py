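"""Markov state space, per-cycle transition matrices, and cohort propagation.

The health-state structure is hierarchical: once a patient has fractured,
only fractures of equal or greater severity (NHNV < vertebral < hip) can
follow. Each fracture type enters a two-cycle first-year "tunnel"
(``*_y1a`` then ``*_y1b``) so that first-year utility multipliers, costs and
mortality relative risks span exactly twelve months on a six-month cycle,
after which the cohort settles into the corresponding post-fracture state.

States (in order)::

    well,
    hip_y1a,  hip_y1b,  post_hip,
    vert_y1a, vert_y1b, post_vert,
    nhnv_y1a, nhnv_y1b, post_nhnv,
    dead

Allowed new-fracture targets by current position in the hierarchy:

* ``well`` and the NHNV states: hip, vertebral, NHNV;
* the vertebral states: hip, vertebral;
* the hip states: hip only;
* ``dead`` is absorbing.

A new fracture while inside a tunnel restarts the first-year clock in the
new fracture's ``y1a`` state (subject to the hierarchy).

Within a cycle, competing risks are resolved death-first: the death
probability is assigned, then fracture probabilities are scaled by
``1 - p_death`` so each row is exactly stochastic without truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .config import SITES, ModelConfig, Site, incidence_for_age

STATES: tuple[str, ...] = (
    "well",
    "hip_y1a",
    "hip_y1b",
    "post_hip",
    "vert_y1a",
    "vert_y1b",
    "post_vert",
    "nhnv_y1a",
    "nhnv_y1b",
    "post_nhnv",
    "dead",
)
N_STATES = len(STATES)
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
DEAD = STATE_INDEX["dead"]

#: Entry (tunnel) state for an incident fracture at each site.
TUNNEL_ENTRY: dict[str, str] = {"hip": "hip_y1a", "vertebral": "vert_y1a", "nhnv": "nhnv_y1a"}

#: Hierarchy mask: which fracture sites each live state may still sustain.
ALLOWED_SITES: dict[str, tuple[str, ...]] = {
    "well": ("hip", "vertebral", "nhnv"),
    "hip_y1a": ("hip",),
    "hip_y1b": ("hip",),
    "post_hip": ("hip",),
    "vert_y1a": ("hip", "vertebral"),
    "vert_y1b": ("hip", "vertebral"),
    "post_vert": ("hip", "vertebral"),
    "nhnv_y1a": ("hip", "vertebral", "nhnv"),
    "nhnv_y1b": ("hip", "vertebral", "nhnv"),
    "post_nhnv": ("hip", "vertebral", "nhnv"),
}

#: Where residual (no new event) mass goes: tunnels advance, others stay.
RESIDUAL_TARGET: dict[str, str] = {
    "well": "well",
    "hip_y1a": "hip_y1b",
    "hip_y1b": "post_hip",
    "post_hip": "post_hip",
    "vert_y1a": "vert_y1b",
    "vert_y1b": "post_vert",
    "post_vert": "post_vert",
    "nhnv_y1a": "nhnv_y1b",
    "nhnv_y1b": "post_nhnv",
    "post_nhnv": "post_nhnv",
}

#: (site, period) whose mortality RR applies in each live state; None -> RR 1.
_STATE_MORTALITY: dict[str, tuple[str, str] | None] = {
    "well": None,
    "hip_y1a": ("hip", "first"),
    "hip_y1b": ("hip", "first"),
    "post_hip": ("hip", "subsequent"),
    "vert_y1a": ("vertebral", "first"),
    "vert_y1b": ("vertebral", "first"),
    "post_vert": ("vertebral", "subsequent"),
    "nhnv_y1a": ("nhnv", "first"),
    "nhnv_y1b": ("nhnv", "first"),
    "post_nhnv": ("nhnv", "subsequent"),  # validated to be exactly 1
}


class MarkovError(ValueError):
    """Raised when inputs produce an ill-formed transition row."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered state list plus the allowed-transition mask."""

    states: tuple[str, ...]
    mask: np.ndarray  # bool (n, n); True where a transition may carry mass

    def index(self, state: str) -> int:
        return STATE_INDEX[state]


def build_state_space() -> StateSpace:
    """Construct the 11-state hierarchical space and its transition mask."""
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    for state in STATES[:-1]:
        i = STATE_INDEX[state]
        mask[i, STATE_INDEX[RESIDUAL_TARGET[state]]] = True
        for site in ALLOWED_SITES[state]:
            mask[i, STATE_INDEX[TUNNEL_ENTRY[site]]] = True
        mask[i, DEAD] = True
    mask[DEAD, DEAD] = True
    return StateSpace(states=STATES, mask=mask)


def prob_rate_convert(p: float, t_from: float, t_to: float) -> float:
    """Re-express probability ``p`` over duration ``t_from`` as one over ``t_to``.

    Assumes a constant hazard: ``1 - (1 - p) ** (t_to / t_from)``.
    """
    if not (0.0 <= p < 1.0):
        raise MarkovError(f"probability must be in [0, 1) for rate conversion, got {p}")
    if t_from <= 0 or t_to <= 0:
        raise MarkovError("durations must be positive")
    return 1.0 - (1.0 - p) ** (t_to / t_from)


def _half_cycle_death(q_annual: float) -> float:
    if q_annual >= 1.0:
        return 1.0
    return prob_rate_convert(q_annual, 1.0, 0.5)


@dataclass(frozen=True)
class TransitionMatrix:
    """One cycle's transition matrix plus the incident-fracture components.

    ``event_probs[s, k]`` is the probability that a patient in state ``s``
    sustains an incident fracture at site ``SITES[k]`` during the cycle;
    these flows are already included in ``matrix`` (they land in the
    corresponding ``y1a`` tunnel) but are kept separately so refractures
    that re-enter the same tunnel are still counted as events.
    """

    matrix: np.ndarray  # (n, n), rows sum to 1
    event_probs: np.ndarray  # (n, len(SITES))


def transition_matrix(
    cycle: int,
    age: float,
    rr_by_site: Mapping[str, float],
    inputs: ModelConfig,
) -> TransitionMatrix:
    """Build the transition matrix for one cycle and one efficacy profile.

    ``rr_by_site`` holds the subcohort's effective fracture relative risks
    for this cycle (1.0 when untreated or fully offset). Death is assigned
    first from the life table scaled by the state's post-fracture mortality
    RR; fracture probabilities are the RR-scaled six-month incidences scaled
    by the survival complement; residual mass advances tunnels or stays put.
    """
    mort = inputs.mortality
    q_base = _half_cycle_death(mort.annual_death_probability(age))

    p6 = {
        site: prob_rate_convert(incidence_for_age(inputs.epidemiology, age, site), 1.0, 0.5)
        for site in SITES
    }

    m = np.zeros((N_STATES, N_STATES))
    events = np.zeros((N_STATES, len(SITES)))
    for state in STATES[:-1]:
        i = STATE_INDEX[state]
        key = _STATE_MORTALITY[state]
        if key is None:
            rr_mort = 1.0
        else:
            site, period = key
            rr_mort = (mort.rr_first_year if period == "first" else mort.rr_subsequent)[site]
        p_death = min(1.0, q_base * rr_mort)

        fracture = {site: rr_by_site[site] * p6[site] for site in ALLOWED_SITES[state]}
        total_frac = sum(fracture.values())
        if total_frac > 1.0:
            raise MarkovError(
                f"fracture probabilities from state {state!r} sum to {total_frac:.4f} > 1 "
                "before competing-risk scaling; inputs are pathological"
            )

        m[i, DEAD] = p_death
        surv = 1.0 - p_death
        for site, p in fracture.items():
            j = STATE_INDEX[TUNNEL_ENTRY[site]]
            m[i, j] += surv * p
            events[i, SITES.index(site)] = surv * p
        m[i, STATE_INDEX[RESIDUAL_TARGET[state]]] += surv * (1.0 - total_frac)
    m[DEAD, DEAD] = 1.0
    return TransitionMatrix(matrix=m, event_probs=events)


@dataclass
class CohortTrace:
    """State occupancies over cycles plus incident-fracture counters.

    ``occupancy[c]`` is the distribution after cycle ``c`` (row 0 is the
    initial distribution); ``events[c - 1, k]`` is the fraction of the
    initial cohort sustaining an incident ``SITES[k]`` fracture during
    cycle ``c`` (refractures included, normalised to the initial cohort).
    """

    occupancy: np.ndarray  # (n_cycles + 1, N_STATES)
    events: np.ndarray  # (n_cycles, len(SITES))
    start_age: float | None = field(default=None)

    @property
    def n_cycles(self) -> int:
        return self.events.shape[0]

    def alive(self, cycle: int) -> float:
        return float(1.0 - self.occupancy[cycle, DEAD])

    def cumulative_events(self, site: Site, through_cycle: int | None = None) -> float:
        """Incident events per initial cohort member through ``through_cycle``."""
        k = SITES.index(site)
        end = self.n_cycles if through_cycle is None else through_cycle
        return float(self.events[:end, k].sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy occupancy export: one row per (cycle, state)."""
        rows = []
        for c in range(self.occupancy.shape[0]):
            age = None if self.start_age is None else self.start_age + 0.5 * c
            for s, occ in zip(STATES, self.occupancy[c]):
                rows.append({"cycle": c, "age": age, "state": s, "occupancy": occ})
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        """Tidy incident-event export: one row per (cycle, site)."""
        rows = []
        for c in range(1, self.n_cycles + 1):
            for k, site in enumerate(SITES):
                rows.append({"cycle": c, "site": site, "incident_fraction": self.events[c - 1, k]})
        return pd.DataFrame(rows)


def run_cohort(
    initial: np.ndarray,
    matrix_provider: Callable[[int], TransitionMatrix],
    n_cycles: int,
    start_age: float | None = None,
) -> CohortTrace:
    """Propagate an initial distribution through ``n_cycles`` transitions.

    ``matrix_provider(cycle)`` supplies the matrix for 1-based ``cycle``.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise MarkovError(f"initial distribution must have shape ({N_STATES},)")
    if abs(initial.sum() - 1.0) > 1e-9 or (initial < 0).any():
        raise MarkovError("initial distribution must be nonnegative and sum to 1")

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    events = np.zeros((n_cycles, len(SITES)))
    occupancy[0] = initial
    for c in range(1, n_cycles + 1):
        tm = matrix_provider(c)
        occupancy[c] = occupancy[c - 1] @ tm.matrix
        events[c - 1] = occupancy[c - 1] @ tm.event_probs
    return CohortTrace(occupancy=occupancy, events=events, start_age=start_age)
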