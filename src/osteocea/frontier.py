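"""Cost-effectiveness frontier: ranking, dominance, ICERs, net monetary benefit.

Strategies are rank-ordered by increasing cost; a strategy is (strictly)
dominated when a cheaper alternative yields at least as many QALYs.
Incremental cost-effectiveness ratios are computed successively along the
surviving frontier. Extended dominance (a higher ICER than the next more
effective option, i.e. dominance by a convex combination of neighbours) is
flagged; flagged strategies are excluded from the successive-ICER chain
only on request, since the base analysis removes simple dominance only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .outcomes import StrategyTotals

REFERENCE = "reference"
ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"


class FrontierError(ValueError):
    pass


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost per unit of incremental effect.

    Requires a positive effect difference; non-positive differences mean
    dominance and must be handled by the caller.
    """
    if delta_effect <= 0:
        raise FrontierError(
            "ICER undefined for non-positive incremental effect; compute dominance instead"
        )
    return delta_cost / delta_effect


def nmb(cost: float, qalys: float, threshold: float) -> float:
    """Net monetary benefit at a willingness-to-pay ``threshold`` (USD/QALY)."""
    if threshold < 0:
        raise FrontierError("threshold must be >= 0")
    return threshold * qalys - cost


@dataclass
class CEARow:
    name: str
    cost: float
    qalys: float
    lys: float
    status: str
    incr_cost: float | None = None
    incr_qalys: float | None = None
    incr_lys: float | None = None
    icer_per_qaly: float | None = None
    icer_per_ly: float | None = None


@dataclass
class CEATable:
    """Frontier-ordered cost-effectiveness table (cheapest first)."""

    rows: list[CEARow]

    def row(self, name: str) -> CEARow:
        for r in self.rows:
            if r.name == name:
                return r
        raise FrontierError(f"no strategy named {name!r} in the CEA table")

    def frontier_names(self) -> list[str]:
        return [r.name for r in self.rows if r.status in (REFERENCE, ON_FRONTIER)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def frontier(
    totals: list[StrategyTotals], exclude_extended: bool = False
) -> CEATable:
    """Rank strategies, mark dominance, and compute successive ICERs.

    Cost ties are broken by higher QALYs, then name, so the output is
    deterministic and invariant to input order. With ``exclude_extended``
    the successive-ICER chain is recomputed after removing extendedly
    dominated strategies; by default they are only flagged.
    """
    names = [t.name for t in totals]
    if len(set(names)) != len(names):
        raise FrontierError(f"duplicate strategy names: {names}")
    if len(totals) < 2:
        raise FrontierError("need at least two strategies")

    order = sorted(totals, key=lambda t: (t.cost, -t.qalys, t.name))
    rows = [CEARow(t.name, t.cost, t.qalys, t.lys, status=ON_FRONTIER) for t in order]

    # simple dominance: at least as many QALYs available for less (or equal
    # cost with the tie-break preferring the earlier row)
    best_q = -math.inf
    for i, r in enumerate(rows):
        if i > 0 and r.qalys <= best_q:
            r.status = DOMINATED
        else:
            best_q = r.qalys
    survivors = [r for r in rows if r.status != DOMINATED]
    survivors[0].status = REFERENCE

    def chain(members: list[CEARow]) -> None:
        for prev, cur in zip(members, members[1:]):
            cur.incr_cost = cur.cost - prev.cost
            cur.incr_qalys = cur.qalys - prev.qalys
            cur.incr_lys = cur.lys - prev.lys
            cur.icer_per_qaly = icer(cur.incr_cost, cur.incr_qalys)
            cur.icer_per_ly = (
                icer(cur.incr_cost, cur.incr_lys) if cur.incr_lys > 0 else None
            )

    chain(survivors)

    # extended dominance: ICER exceeds the next (more effective) member's
    if exclude_extended:
        while True:
            active = [r for r in survivors if r.status in (REFERENCE, ON_FRONTIER)]
            flagged = False
            for cur, nxt in zip(active[1:], active[2:]):
                if cur.icer_per_qaly > nxt.icer_per_qaly:
                    cur.status = EXTENDEDLY_DOMINATED
                    flagged = True
                    break
            if not flagged:
                break
            chain([r for r in survivors if r.status in (REFERENCE, ON_FRONTIER)])
    else:
        for cur, nxt in zip(survivors[1:], survivors[2:]):
            if cur.icer_per_qaly > nxt.icer_per_qaly:
                cur.status = EXTENDEDLY_DOMINATED

    return CEATable(rows=rows)
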