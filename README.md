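# osteocea

A lifetime Markov cohort cost-effectiveness model of osteoporosis
treatments in elderly men, from the US payer perspective.

The package is aimed at health economists and epidemiological modellers.
It compares denosumab against five comparators — generic alendronate,
risedronate, ibandronate, zoledronate and teriparatide — for a cohort of
osteoporotic men entering at age 78 with a 23% prevalence of vertebral
fracture, and reports discounted lifetime costs (2013 USD), QALYs,
life-years, 10-year fracture risks, the incremental cost-effectiveness
frontier, and one-way and probabilistic sensitivity analyses.

## Model

The cohort moves through a hierarchical fracture state space on 6-month
cycles: `well`, first-year hip / clinical vertebral / non-hip-non-vertebral
(NHNV) fracture tunnels (two cycles each), the corresponding post-fracture
states, and `dead`. Once fractured, a patient can only sustain fractures of
equal or greater severity (NHNV < vertebral < hip): post-hip patients may
only refracture the hip; vertebral patients may sustain hip or vertebral
fractures only.

Per cycle and state, the death probability is the 6-month background
probability q(a) from a male life table times a post-fracture mortality
relative risk (higher in the first year after fracture; NHNV raises
mortality in the first year only). Fracture probabilities are
constant-hazard conversions of age-banded annual incidences h(a), scaled by
the strategy's effective relative risk RR(t) and by the survival complement
(death is resolved first):

    p_frac(site) = RR_site(t) · [1 − (1 − h_site(a))^½] · (1 − p_death)

Treatment dynamics: each strategy's cohort is partitioned exactly into
discontinuation-time subcohorts using 6-month discontinuation
probabilities over the first three years (orals use the schedule directly;
injectables transform it through the discontinuation hazard ratio 0.5 via
`p' = 1 − (1 − p)^HR`). Survivors of year 3 persist to planned termination
(5 years; teriparatide 2). After stopping, RR decays linearly to 1 over an
offset time capped by the time on treatment (first-cycle dropouts get no
offset).

Accounting: costs (drug, administration and monitoring while on treatment;
first-year fracture costs attached to incident events; recurring post-hip
costs; daily-rated long-term care fed by a fraction of incident hip
fractures) and effects (age-specific baseline utility × health-state
multiplier) are discounted at 3%/year. Strategies are ranked by cost,
dominated ones removed, and successive ICERs (Δcost/ΔQALY) computed along
the frontier; the PSA redraws all uncertain parameters (lognormal RRs,
gamma costs, beta utilities/proportions) and summarises cost-effectiveness
acceptability curves by net monetary benefit.

## Worked example

```python
import osteocea as oc

cfg = oc.default_config()          # packaged base case (YAML + CSV tables)
table = oc.run_cea(cfg)            # run all six strategies and rank them
print(table.to_frame()[["name", "cost", "qalys", "status"]].round(4))
```

prints (packaged synthetic fixtures; see note below):

```
               name       cost  qalys               status
generic_alendronate  8684.7964 5.4159            reference
        ibandronate 11827.9144 5.4066            dominated
        risedronate 12196.0397 5.4108            dominated
        zoledronate 12271.9930 5.4214 extendedly_dominated
          denosumab 12474.5072 5.4368          on_frontier
       teriparatide 27163.0939 5.4270            dominated
```

Each row is one strategy's discounted lifetime cost (USD) and QALYs;
`status` marks the cost-effectiveness frontier. Denosumab yields the most
QALYs and is the only active comparator on the frontier; its ICER versus
the cheapest strategy is `table.row("denosumab").icer_per_qaly`
(≈ $13,200/QALY here, i.e. cost-effective at a $100,000/QALY threshold).

Fed the published base-case totals instead, the frontier machinery
reproduces the published worked example exactly:

```python
from osteocea.outcomes import StrategyTotals
ref = [StrategyTotals(r.strategy, cost=r.cost, qalys=r.qalys, lys=r.lys)
       for r in oc.load_reference_results().itertuples()]
row = oc.frontier(ref).row("denosumab")
row.incr_cost, row.incr_qalys, oc.round_to_hundred(row.icer_per_qaly)
# (878.0, 0.0520, 16900.0)
```

— an incremental cost of $878 and 0.0520 incremental QALYs for denosumab
versus generic alendronate, i.e. $16,900 per QALY gained.

The same analyses are available from the shell:

```bash
osteo-cea run --out results/            # CEA table, risks, cost breakdown
osteo-cea dsa --out results/            # tornado table
osteo-cea psa --draws 1000 --seed 1 --out results/   # PSA draws + CEAC
osteo-cea fixtures --out config/        # write editable config + tables
```

Note: absolute cost/QALY magnitudes depend on inputs the original analysis
did not publish (life table, persistence schedule, post-fracture mortality,
baseline utilities, long-term-care admission). The packaged fixtures are
clearly provenance-flagged synthetic stand-ins, so absolute totals differ
from the published ones even though the model structure and all printed
parameters match; `docs/methods.md` discusses what the fixtures do and do
not emulate.

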