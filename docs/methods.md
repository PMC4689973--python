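# Methods

## Model structure

The model is a cohort Markov chain on 6-month cycles over a lifetime
horizon (age 78 to 110, 64 cycles). The eleven states are `well`, two-cycle
first-year tunnels for hip, clinical vertebral, and non-hip-non-vertebral
(NHNV) fracture (`*_y1a`, `*_y1b`), the corresponding chronic post-fracture
states, and absorbing `dead`. The tunnels exist so that "first year after
fracture" quantities — utility multipliers, first-year mortality relative
risks — span exactly twelve months on a 6-month cycle.

Fracture severity is hierarchical (NHNV < vertebral < hip) and downward
transitions are structurally impossible: post-hip patients may only
refracture the hip; vertebral-state patients may sustain hip or vertebral
fractures; well and NHNV-state patients may sustain any fracture. A new
fracture while still inside a first-year tunnel restarts the clock in the
new fracture's `y1a` state (the alternative — continuing the old clock — is
not distinguishable from published descriptions of this model family; the
restart keeps first-year semantics exact and is the implemented choice).

The initial distribution places the prevalent-vertebral-fracture share
(23%) in the post-vertebral state and the remainder in `well`, so the
hierarchy correctly blocks their milder fractures from the start.

## Transition probabilities

Annual quantities are converted to 6-month probabilities under a constant
hazard: `p6 = 1 − (1 − p1)^½`. Within a cycle, competing risks are resolved
death-first: the death probability is assigned, then fracture probabilities
are multiplied by the survival complement, and residual mass advances the
tunnel (or stays put), making every row exactly stochastic without
truncation or renormalisation. If the raw fracture probabilities alone sum
above 1 the engine raises an error rather than silently renormalising —
that situation signals pathological inputs.

The state death probability is the life-table 6-month probability times
the applicable post-fracture mortality relative risk (first-year RR in the
tunnels, subsequent-year RR in post-hip/post-vertebral, 1 elsewhere),
capped at 1. The cap can only bind in the last few cycles before the
terminal age, where the life table itself approaches 1.

No half-cycle correction is applied in the base case; occupancy "during" a
cycle is the end-of-cycle distribution. Incident events are counted on
every entry into a `y1a` tunnel — including same-state refractures — and
are normalised to the initial cohort.

## Treatment persistence, subcohorts, and offset

Premature discontinuation can occur at the start of each of the first six
cycles (three years), after which patients persist to planned termination
(5 years; 2 for teriparatide). Oral strategies use the packaged 6-month
discontinuation schedule directly; injectables (denosumab, teriparatide,
zoledronate) transform each probability through the discontinuation hazard
ratio (0.5) with `p' = 1 − (1 − p)^HR`, which makes k-cycle persistence
satisfy the proportional-hazards identity `S_inj = S_oral^HR` exactly.

Because discontinuation is independent of health state, the cohort
decomposes exactly into discontinuation-time subcohorts whose weights are
fixed at baseline (sequential products of persistence). Each subcohort is
simulated with its own per-cycle effective relative-risk profile and the
results are weight-averaged; this is algebraically identical to expanding
the state space by treatment status, at a fraction of the cost.

After stopping, the fracture relative risk decays **linearly** from the
on-treatment value to 1 over the offset time. The offset duration is capped
by the time actually on treatment, rounded up to whole years (stopping "by
year 1" earns a one-year offset); patients who drop out in the very first
cycle receive no offset; completers receive `min(offset, treatment
duration)`. The decay is evaluated at each off-treatment cycle's midpoint.
The linear shape is a modelling choice (a step function is the obvious
alternative); the duration rules, not the shape, are what published
descriptions fix.

Drug, administration and monitoring costs stop at discontinuation;
fracture and long-term-care costs always continue.

## Accounting

Discounting is annual (3% base case for both costs and effects), applied
per cycle as `(1 + r)^(−c/2)`.

Cost components per cycle:

* **drug** — annual acquisition cost × ½ × alive fraction, while on
  treatment;
* **admin + monitoring** — strategy administration events (nurse visits
  for denosumab, IV administration for zoledronate) plus BMD measurement
  (every 2 years) and physician visits (annual), same accrual rule;
* **first-year fracture** — the full year-1 cost attached once to each
  incident event, so the two-cycle tunnel cannot double-count;
* **subsequent hip** — an annual cost recurring while in post-hip
  (recurrence every year, not year-2 only, is the implemented reading of
  "subsequent years"); vertebral and NHNV fractures carry no cost beyond
  year 1;
* **long-term care** — a fixed fraction (0.20, placeholder) of incident
  hip fractures enters a permanent LTC pool costed at $236/day ×
  182.625 days/cycle. The pool decays with post-hip subsequent-year
  mortality for all members, including those admitted within the last
  year; exact first-year tracking would need an admission-age expansion
  disproportionate to a placeholder parameter.

QALYs weight end-of-cycle occupancy by the age-specific baseline utility
times the state multiplier (hip 0.700 year 1 / 0.800 later; vertebral
0.590 / 0.930; NHNV 0.902 / 1.0); LYs use weight 1, so unit utilities make
QALYs equal LYs exactly. 10-year fracture risks are undiscounted cumulative
incident-event fractions over cycles 1–20; counting all events (not first
events only) is configurable at the trace level via the event counters.

## Frontier and sensitivity analyses

Strategies are sorted by cost (ties: higher QALYs, then name). A strategy
is dominated when an earlier-sorted strategy has at least its QALYs.
Successive ICERs are computed along the survivors; extended dominance
(ICER above the next member's) is flagged but excluded from the chain only
on request, since the base analysis removes simple dominance only. ICERs
are stored unrounded; the report layer rounds to the nearest $100.

The one-way DSA varies one parameter at a time to low/high bounds
(published CI for the denosumab hip RR, otherwise ±25%) and records the
pairwise denosumab-vs-alendronate ICER at each bound, sorted by range
width. Named scenarios cover generic zoledronate (−35%), generic
risedronate (−65%), long comparator offsets (5y; teriparatide 2.5y;
denosumab 2y) and a 1-year denosumab offset.

The PSA samples all uncertain parameters independently — lognormal for
relative risks and the hazard ratio, gamma for costs, beta for utility
multipliers and the LTC admission fraction, with SE defaulting to 25% of
the mean (utility multipliers use SE 0.05 so that method-of-moments beta
parameters stay well-defined near 1) and zero SE meaning a point mass.
Draws are parameter-major from per-parameter streams spawned off a single
seed, so adding a parameter never perturbs the other streams. CEACs assign
each draw to the strategy with maximal net monetary benefit (exact ties
split equally), giving probabilities that partition to 1 at every
threshold.

## Synthetic fixtures: what they emulate, and what passing tests show

All printed base-case parameters (treatment relative risks, age-banded
incidence, utility multipliers, unit costs, population, discounting) ship
verbatim in the packaged configuration and are provenance-flagged `paper`.
Four inputs the original analysis used but never published are regenerated
as provenance-flagged `placeholder` fixtures:

* **life table** — Gompertz–Makeham, `h(a) = 7e−4 + 3e−5·e^(0.095a)`,
  giving q(78) ≈ 0.049 and a remaining life expectancy at 78 of ≈ 9.7
  years, forced to q = 1 at 110;
* **persistence schedule** — (0.300, 0.226, 0.10, 0.08, 0.06, 0.05); the
  first two cycles are calibrated so the HR-0.5 transform gives 73.6%
  one-year denosumab persistence, the tail is a declining-hazard
  placeholder;
* **post-fracture mortality RRs** — hip 3.0/1.8, vertebral 2.5/1.5, NHNV
  1.4/1.0 (first year / subsequent);
* **baseline utilities** — linear from 0.80 at 78 to 0.60 at 110;
* the LTC admission fraction (0.20) is likewise a placeholder.

These fixtures reproduce the *structure* the analysis assumes, not the
original numbers, and nothing was tuned toward the published cost/QALY
totals. Consequently the packaged base case reproduces the published
qualitative picture only partially: generic alendronate is cheapest,
denosumab accrues the most QALYs, has the lowest 10-year hip risk, and is
the only active comparator on the frontier — but absolute totals and risks
are well below the published ones. In particular, the published 10-year
hip risk (≈ 0.16 untreated) is about three times what the printed
incidence table can generate under any mortality assumption, implying the
original background-risk calculation amplified the printed rates (a
cohort-risk derivation published separately and deliberately out of scope
here). With fracture burden at the printed rates, averted-fracture savings
no longer offset denosumab's drug cost, so denosumab is not second-cheapest
under the packaged fixtures; the corresponding qualitative regression
tests document this gap rather than hide it. Passing tests therefore
demonstrate correctness of the machinery (probability conversion, mass
conservation, hierarchy, accounting identities, frontier arithmetic,
PSA reproducibility) and exact reproduction of the published worked
examples — not recovery of the published absolute totals, which requires
dropping in the real unpublished inputs (the CSV schemas accept them
unchanged).

## Numerical choices and degenerate inputs

* Probability/rate conversions reject p ≥ 1; the terminal life-table row
  is handled as certain death.
* Transition rows sum to 1 to ≤ 1e−12 by construction; cohort mass is
  conserved to ≤ 1e−10 over 64 cycles.
* Zero incidence, zero discount rates, unit utilities, zero-width DSA
  bounds and zero-dispersion PSA specs are all legal degenerate inputs and
  reduce to the expected closed forms.
* Cost ties on the frontier are broken deterministically (QALYs, then
  name); frontier output is invariant to input order.
* Problem sizes: the default analysis is 6 strategies × 7 subcohorts × 64
  cycles (< 0.1 s); the packaged PSA default is 1,000 draws, and the test
  suite exercises the PSA at up to 50 draws, which is ample for the
  structural properties it checks.

## Known limitations

* No microsimulation; no sequential or pre-treated therapy; persistence is
  binary on/off (no partial adherence); no correlated PSA sampling; no
  value-of-information analysis; payer perspective only.
* Discontinuation is applied at cycle start (a cycle-end convention would
  shift drug costs and offsets by one cycle); this is configurable only by
  editing the subcohort construction.
* The LTC pool's mortality approximation (subsequent-year RR for all
  members) slightly overstates LTC survival in the first year after
  admission.
* Published headline totals are not reproducible from printed inputs alone
  (see the fixtures section above).
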