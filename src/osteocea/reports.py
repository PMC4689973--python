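"""Human-readable report tables mirroring the analysis outputs.

Assembles the cost-effectiveness table, the 10-year fracture-risk table,
the disaggregated cost table, and (when available) the tornado and CEAC
tables into one bundle, serialised as CSV, JSON and Markdown. Monetary
values are stored unrounded; only the display layer rounds (ICERs to the
nearest $100, matching the convention of narrative cost-effectiveness
reporting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import SITES
from .frontier import CEATable
from .outcomes import COST_COMPONENTS, StrategyTotals


def round_to_hundred(x: float) -> float:
    """Round to the nearest $100 (display convention for headline ICERs)."""
    return round(x / 100.0) * 100.0


@dataclass
class ReportBundle:
    cea: pd.DataFrame
    ten_year_risk: pd.DataFrame
    disaggregated_costs: pd.DataFrame
    tornado: pd.DataFrame | None = None
    ceac: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "cea": self.cea,
            "ten_year_risk": self.ten_year_risk,
            "disaggregated_costs": self.disaggregated_costs,
        }
        if self.tornado is not None:
            out["tornado"] = self.tornado
        if self.ceac is not None:
            out["ceac"] = self.ceac
        return out


def build_report(
    totals: list[StrategyTotals],
    table: CEATable,
    tornado: pd.DataFrame | None = None,
    ceac: pd.DataFrame | None = None,
) -> ReportBundle:
    """Assemble the report tables from computed totals and the CEA ranking."""
    risks = pd.DataFrame(
        [{"strategy": t.name, **{s: t.ten_year_risk.get(s) for s in SITES}} for t in totals]
    )
    costs = pd.DataFrame(
        [
            {
                "strategy": t.name,
                **{c: t.components.get(c, 0.0) for c in COST_COMPONENTS},
                "total": t.cost,
            }
            for t in totals
        ]
    )
    return ReportBundle(
        cea=table.to_frame(),
        ten_year_risk=risks,
        disaggregated_costs=costs,
        tornado=tornado,
        ceac=ceac,
    )


def markdown_report(bundle: ReportBundle) -> str:
    """Markdown rendering with display rounding applied."""
    lines = ["# Cost-effectiveness results", "", "## CEA table (discounted, lifetime)", ""]
    cea = bundle.cea.copy()
    for col in ("icer_per_qaly", "icer_per_ly"):
        cea[col] = cea[col].map(
            lambda v: "" if v is None or pd.isna(v) else f"${round_to_hundred(v):,.0f}"
        )
    cea["cost"] = cea["cost"].map(lambda v: f"${v:,.0f}")
    lines.append(cea.to_markdown(index=False))
    lines += ["", "## 10-year fracture risk", "", bundle.ten_year_risk.round(3).to_markdown(index=False)]
    lines += ["", "## Disaggregated discounted costs", "", bundle.disaggregated_costs.round(0).to_markdown(index=False)]
    if bundle.tornado is not None:
        lines += ["", "## One-way sensitivity (tornado)", "", bundle.tornado.round(1).to_markdown(index=False)]
    if bundle.ceac is not None:
        lines += ["", "## Cost-effectiveness acceptability", "", bundle.ceac.round(3).to_markdown(index=False)]
    return "\n".join(lines) + "\n"


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write every table as CSV plus a combined JSON and Markdown report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    combined = {}
    for name, frame in bundle.tables().items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        written.append(p)
        combined[name] = json.loads(frame.to_json(orient="records"))
    jp = outdir / "report.json"
    jp.write_text(json.dumps(combined, indent=2))
    written.append(jp)
    mp = outdir / "report.md"
    mp.write_text(markdown_report(bundle))
    written.append(mp)
    return written


def plot_tornado(tornado: pd.DataFrame, path: str | Path, base_icer: float | None = None) -> None:
    """Horizontal-bar tornado plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tornado.iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(df) + 1.5))
    for i, (_, row) in enumerate(df.iterrows()):
        lo, hi = sorted((row["icer_low"], row["icer_high"]))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.set_yticks(range(len(df)), df["parameter"])
    if base_icer is not None:
        ax.axvline(base_icer, color="k", lw=1, ls="--")
    ax.set_xlabel("pairwise ICER (USD/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac: pd.DataFrame, path: str | Path) -> None:
    """Acceptability curves: probability cost-effective vs threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for name, grp in ceac.groupby("strategy"):
        ax.plot(grp["threshold"], grp["probability"], label=name)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
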