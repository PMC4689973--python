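"""Deterministic and probabilistic sensitivity analyses.

One-way DSA varies a single parameter to its low/high bound (published CI
when available, otherwise ±25% of base) and records the pairwise ICER of a
reference strategy pair at each bound, producing a tornado table. Named
scenarios rerun the full model under grouped overrides (generic pricing,
alternative offset times). The PSA redraws all uncertain parameters jointly
from support-appropriate distributions (lognormal for relative risks and
hazard ratios, gamma for costs, beta for utilities and proportions), reruns
the model per draw, and summarises results as cost-effectiveness
acceptability curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .config import ModelConfig, get_parameter, with_parameters
from .frontier import nmb
from .model import run_all, run_cea
from .outcomes import StrategyTotals


class SensitivityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis (tornado)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DSASpec:
    """One tornado bar: a parameter path and its low/high bounds."""

    path: str
    low: float
    high: float
    label: str = ""

    def __post_init__(self):
        if self.low > self.high:
            raise SensitivityError(f"DSA spec {self.path}: low {self.low} > high {self.high}")
        if not self.label:
            object.__setattr__(self, "label", self.path)

    @classmethod
    def pct(cls, path: str, base: float, rel: float = 0.25, label: str = "") -> "DSASpec":
        """Symmetric ±``rel`` bounds around ``base`` (the default convention)."""
        return cls(path=path, low=base * (1 - rel), high=base * (1 + rel), label=label)


def default_dsa_specs(config: ModelConfig) -> list[DSASpec]:
    """The packaged tornado parameters for the denosumab-vs-alendronate pair.

    The denosumab hip relative risk uses its published confidence interval
    (0.18-0.78); everything else is varied ±25% around base.
    """
    g = lambda p: get_parameter(config, p)
    specs = [
        DSASpec("strategies.denosumab.rr_hip", 0.18, 0.78, label="denosumab RR hip (95% CI)"),
        DSASpec.pct("strategies.generic_alendronate.rr_hip", g("strategies.generic_alendronate.rr_hip")),
        DSASpec.pct("strategies.denosumab.annual_drug_cost", g("strategies.denosumab.annual_drug_cost")),
        DSASpec.pct("costs.ltc_daily", g("costs.ltc_daily")),
        DSASpec.pct("costs.ltc_admission_fraction", g("costs.ltc_admission_fraction")),
        DSASpec.pct("costs.fracture_year1.hip", g("costs.fracture_year1.hip")),
        DSASpec.pct("strategies.denosumab.hazard_ratio", g("strategies.denosumab.hazard_ratio")),
        DSASpec.pct("strategies.denosumab.rr_vert", g("strategies.denosumab.rr_vert")),
    ]
    return specs


def pairwise_icer(
    totals: list[StrategyTotals], intervention: str, comparator: str
) -> tuple[float, str]:
    """ICER (and dominance label) of ``intervention`` versus ``comparator``.

    Returns ``(ratio, flag)`` where ``flag`` is ``"icer"`` for a regular
    ratio, ``"dominant"`` when the intervention is cheaper and more
    effective, and ``"dominated"`` when it is costlier and less effective.
    The raw ratio is kept in all cases for bar-width bookkeeping.
    """
    by_name = {t.name: t for t in totals}
    ti, tc = by_name[intervention], by_name[comparator]
    dc, dq = ti.cost - tc.cost, ti.qalys - tc.qalys
    ratio = dc / dq if dq != 0 else math.inf * (1 if dc >= 0 else -1)
    if dq > 0:
        flag = "dominant" if dc < 0 else "icer"
    else:
        flag = "dominated" if dc > 0 else "icer"
    return ratio, flag


def one_way_dsa(
    config: ModelConfig,
    specs: list[DSASpec],
    reference_pair: tuple[str, str] = ("denosumab", "generic_alendronate"),
) -> pd.DataFrame:
    """Tornado table: pairwise ICER at each parameter's low and high bound.

    Rows are sorted by the width of the ICER range, widest (most
    influential) first.
    """
    intervention, comparator = reference_pair
    config.strategy(intervention), config.strategy(comparator)  # existence check
    rows = []
    for spec in specs:
        result = {}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            totals = run_all(with_parameters(config, {spec.path: value}))
            ratio, flag = pairwise_icer(totals, intervention, comparator)
            result[f"icer_{bound}"] = ratio
            result[f"flag_{bound}"] = flag
        rows.append(
            {
                "parameter": spec.label,
                "path": spec.path,
                "low_value": spec.low,
                "high_value": spec.high,
                **result,
                "width": abs(result["icer_high"] - result["icer_low"]),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("width", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------


def scenario(config: ModelConfig, overrides: dict[str, float]):
    """Full CEA rerun under dotted-path ``overrides`` (empty = base case)."""
    return run_cea(with_parameters(config, overrides))


def packaged_scenarios(config: ModelConfig) -> dict[str, dict[str, float]]:
    """The shipped scenario set.

    * ``generic_zoledronate`` / ``generic_risedronate``: acquisition cost
      reduced by 35% / 65% of the branded price;
    * ``long_offset``: offset times of 2y (denosumab), 2.5y (teriparatide),
      5y (all other comparators);
    * ``short_denosumab_offset``: denosumab offset reduced to 1 year.
    """
    g = lambda p: get_parameter(config, p)
    long_offset = {
        f"strategies.{s.name}.offset_years": 5.0
        for s in config.strategies
        if s.name not in ("denosumab", "teriparatide")
    }
    long_offset["strategies.denosumab.offset_years"] = 2.0
    long_offset["strategies.teriparatide.offset_years"] = 2.5
    return {
        "generic_zoledronate": {
            "strategies.zoledronate.annual_drug_cost": 0.65
            * g("strategies.zoledronate.annual_drug_cost")
        },
        "generic_risedronate": {
            "strategies.risedronate.annual_drug_cost": 0.35
            * g("strategies.risedronate.annual_drug_cost")
        },
        "long_offset": long_offset,
        "short_denosumab_offset": {"strategies.denosumab.offset_years": 1.0},
    }


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

Family = Literal["lognormal", "gamma", "beta"]


@dataclass(frozen=True)
class PSASpec:
    """One uncertain parameter: distribution family matched to its support.

    ``se`` defaults to 25% of the mean (the same convention as the DSA);
    ``se = 0`` is the degenerate point mass at the mean. A 95% CI may be
    given instead for lognormal parameters, in which case the dispersion is
    derived from the CI width on the log scale.
    """

    path: str
    family: Family
    mean: float
    se: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.mean <= 0 and self.family in ("lognormal", "gamma"):
            raise SensitivityError(f"{self.path}: {self.family} requires a positive mean")
        if self.family == "beta" and not (0.0 < self.mean < 1.0):
            raise SensitivityError(f"{self.path}: beta requires mean in (0, 1)")
        if self.se is None and self.ci is None:
            object.__setattr__(self, "se", 0.25 * abs(self.mean))
        if self.se is not None and self.se < 0:
            raise SensitivityError(f"{self.path}: dispersion must be >= 0")
        if self.ci is not None and self.family != "lognormal":
            raise SensitivityError(f"{self.path}: CI-based dispersion is lognormal-only")
        if self.family == "beta" and self.se is not None and self.se > 0:
            if self.se**2 >= self.mean * (1 - self.mean):
                raise SensitivityError(
                    f"{self.path}: beta dispersion too large for mean {self.mean}"
                )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "lognormal" and self.ci is not None:
            lo, hi = self.ci
            if not (0 < lo < hi):
                raise SensitivityError(f"{self.path}: invalid CI {self.ci}")
            mu = 0.5 * (math.log(lo) + math.log(hi))
            sigma = (math.log(hi) - math.log(lo)) / (2 * 1.959963984540054)
            return rng.lognormal(mu, sigma, n)
        if self.se == 0:
            return np.full(n, self.mean)
        m, s = self.mean, self.se
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + (s / m) ** 2)
            mu = math.log(m) - 0.5 * sigma2
            return rng.lognormal(mu, math.sqrt(sigma2), n)
        if self.family == "gamma":
            shape = (m / s) ** 2
            return rng.gamma(shape, s**2 / m, n)
        # beta by method of moments
        nu = m * (1 - m) / s**2 - 1.0
        return rng.beta(m * nu, (1 - m) * nu, n)


def default_psa_specs(config: ModelConfig) -> list[PSASpec]:
    """The packaged PSA parameter set.

    Uncertain inputs: treatment fracture relative risks (lognormal), the
    discontinuation hazard ratio (lognormal), fracture and nursing-home
    costs (gamma), utility multipliers (beta), and the long-term-care
    admission fraction (beta).
    """
    specs: list[PSASpec] = []
    for s in config.strategies:
        for fieldname in ("rr_hip", "rr_vert", "rr_nhnv"):
            path = f"strategies.{s.name}.{fieldname}"
            specs.append(PSASpec(path, "lognormal", get_parameter(config, path)))
    specs.append(
        PSASpec(
            "strategies.denosumab.hazard_ratio",
            "lognormal",
            get_parameter(config, "strategies.denosumab.hazard_ratio"),
        )
    )
    for site in ("hip", "vertebral", "nhnv"):
        specs.append(
            PSASpec(
                f"costs.fracture_year1.{site}",
                "gamma",
                get_parameter(config, f"costs.fracture_year1.{site}"),
            )
        )
    specs.append(PSASpec("costs.hip_subsequent_annual", "gamma", config.costs.hip_subsequent_annual))
    specs.append(PSASpec("costs.ltc_daily", "gamma", config.costs.ltc_daily))
    specs.append(PSASpec("costs.ltc_admission_fraction", "beta", config.costs.ltc_admission_fraction))
    for site in ("hip", "vertebral", "nhnv"):
        specs.append(
            PSASpec(
                f"utilities.multiplier_year1.{site}",
                "beta",
                config.utilities.multiplier_year1[site],
                se=0.05,
            )
        )
    for site in ("hip", "vertebral"):
        specs.append(
            PSASpec(
                f"utilities.multiplier_later.{site}",
                "beta",
                config.utilities.multiplier_later[site],
                se=0.05,
            )
        )
    return specs


@dataclass
class PSAResult:
    """Per-draw strategy totals plus the sampled parameter matrix."""

    draws: pd.DataFrame  # columns: draw, strategy, cost, qalys, lys
    parameters: pd.DataFrame = field(repr=False, default=None)


def psa(
    config: ModelConfig,
    specs: list[PSASpec],
    n_draws: int,
    seed: int,
) -> PSAResult:
    """Probabilistic sensitivity analysis: joint redraw, full rerun per draw.

    Sampling is parameter-major from per-spec child streams spawned off one
    seed, so draw ``i`` for a given parameter does not depend on how many
    other parameters are in the analysis. Reproducible given ``seed``.
    """
    if n_draws < 1:
        raise SensitivityError("n_draws must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    values = {
        spec.path: spec.sample(np.random.default_rng(stream), n_draws)
        for spec, stream in zip(specs, streams)
    }
    params = pd.DataFrame(values)
    params.insert(0, "draw", range(n_draws))

    rows = []
    for i in range(n_draws):
        overrides = {path: float(col[i]) for path, col in values.items()}
        for t in run_all(with_parameters(config, overrides)):
            rows.append(
                {"draw": i, "strategy": t.name, "cost": t.cost, "qalys": t.qalys, "lys": t.lys}
            )
    return PSAResult(draws=pd.DataFrame(rows), parameters=params)


def ceac(draws: pd.DataFrame, thresholds: np.ndarray | list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each willingness-to-pay threshold, the probability that each
    strategy has the maximal net monetary benefit across draws; exact NMB
    ties within a draw split the probability equally. Probabilities sum to
    1 at every threshold.
    """
    if draws.empty:
        raise SensitivityError("need at least one PSA draw")
    thresholds = np.asarray(thresholds, dtype=float)
    wide_cost = draws.pivot(index="draw", columns="strategy", values="cost")
    wide_q = draws.pivot(index="draw", columns="strategy", values="qalys")
    strategies = list(wide_cost.columns)
    n = len(wide_cost)
    rows = []
    for lam in thresholds:
        benefit = nmb(wide_cost.to_numpy(), wide_q.to_numpy(), lam)
        best = benefit.max(axis=1, keepdims=True)
        winners = np.isclose(benefit, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for s, p in zip(strategies, probs):
            rows.append({"threshold": lam, "strategy": s, "probability": p})
    return pd.DataFrame(rows)
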