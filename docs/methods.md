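# Methods

## Scope and perspective

`hearcost` models the cost of a school-based pediatric hearing screening
campaign from the provider perspective: only expenses borne by the program
are counted, not household or societal costs. The packaged baseline is the
2018 Malindi program — four semi-rural primary schools, five days, 155
teacher-preselected children screened, 32 screen failures, all 32 confirmed
with hearing loss by diagnostic audiometry (9 of them moderate or worse,
the conventional threshold for disabling loss).

The ledger covers one program cycle. No amortization of capital equipment,
discounting, inflation adjustment or currency conversion is applied: the
program spans a single short campaign and the analysis takes no position on
annualizing the capital outlay.

## Cost model

Costs are line items with a category (`capital` = one-time equipment
investment: audiometry software, headphones/phones, otoscopes; `recurrent` =
per-cycle running costs) and a bucket (`equipment`, `medical_supplies`,
`staff`, `transport`, `maintenance`, `resident_travel`). Totals are exact
integer-dollar sums; floating point never enters ledger arithmetic.

Each item stores an explicit value per funding scenario rather than deriving
values from the resident/humanitarian flags, because the observed discounts
are item-specific: the travel grant covered $1,000 of a $1,300 flight, prior
vaccinations saved $42, the software subscription and part of the calibration
fee were waived outright, and teachers volunteered their time in the
actualized scenario. The R/H flags are kept as metadata and *validated*
against the explicit values (a no-resident scenario must zero resident travel
and salary; a humanitarian scenario may never exceed its undiscounted
counterpart item-by-item).

The derived `model2_no_resident` scenario (local program keeping its
humanitarian support) equals `model2` with the resident-travel bucket and the
resident salary zeroed. Its ledger total is $2,879; published program
reports quote $2,880 — a one-dollar arithmetic slip in the source material
($3,988 − $1,109 = $2,879) that the ledger does not reproduce, since every
item is transcribed exactly.

## Effectiveness metrics and rounding conventions

Cost-effectiveness is cost per newly identified case: scenario total divided
by the number of diagnosed children. The default denominator is *any*
hearing loss (n = 32); the $212 and $125 per-case figures only arise under
this reading, so moderate-or-worse (n = 9) is an option, not the default.

Rounding conventions are fixed and explicit because the published figures
mix two rules:

- per-case costs round half away from zero (6,783/32 = 211.97 → 212);
- per-school costs truncate by default (6,783/4 = 1,695.75 → 1,695, the
  value behind the $130,515 projection) with nearest-dollar rounding as a
  documented switch (719.75 → 720, the value behind the $55,440 projection);
  no single rule reproduces both printed projections, so both are
  first-class and every output records which was used;
- percentages are reported to one decimal, half away from zero. 1/155 =
  0.645% therefore prints 0.6 here where some reports show 0.7; tests carry
  a ±0.1-point tolerance for this class of discrepancy.

## One-way sensitivity analysis

Five parameters: capital costs, equipment maintenance, medical supplies, and
staff salaries + ground transportation (grouped, as conventionally reported)
each vary ±20% of their bucket base sum; *economic variation* scales the
entire total ±5% to represent currency fluctuation affecting every element
at once. Resident travel has no sensitivity parameter — it is a known,
contracted expense — and is held at base in every row, including analyses of
the resident-inclusive scenarios.

For a component parameter the bounds are `base ∓ r·(bucket sum)`; for the
economic parameter `base·(1 ∓ 0.05)`. Display totals are rounded to the
nearest dollar; per-case columns are computed from the *unrounded* bounds
and then rounded half away from zero. Published tables of this analysis
round inconsistently (floor in some cells, nearest in others), so
comparisons against them use a ±1 USD tolerance per total cell; per-case
cells match exactly. The tornado order sorts by swing (upper minus lower
total), ties alphabetical.

## Probabilistic sensitivity analysis

Per iteration, every uncertain cost element receives an independent
triangular multiplier `Tri(1−r, 1, 1+r)` with mode 1 (r = 0.20 for the four
component parameters), the perturbed total is multiplied by an independent
global economic factor `Tri(0.95, 1, 1.05)`, resident travel enters
unperturbed, and cost per case is the perturbed total over the fixed case
count. Draws are kept unrounded; rounding inside draws would bias the
interval endpoints. Sampling uses the closed-form triangular inverse CDF
applied to `numpy` Generator uniforms; the default seed is 20181001 and is
logged in every output.

**Granularity.** The default draws one multiplier per ledger *line item*
(`granularity="item"`); `"bucket"` draws one per sensitivity parameter and
applies it to the bucket sum. Item-level noise partially averages out within
multi-item buckets, giving a tighter total distribution; it is the default
because it reproduces the reference program's published 95% intervals for
all three scenarios (≈ $285–331, $116–133, $194–231 per case), which
bucket-level perturbation does not (it widens the no-resident interval to
≈ $186–238). Scientifically it encodes the more plausible assumption that
individual purchase prices vary independently rather than in lock-step per
category.

Intervals are central empirical quantiles (linear interpolation between
order statistics); at 10,000 draws the quantile-method choice moves
endpoints by well under $1, and endpoints vary by ≈ $1–2 across seeds.
All draws lie inside the analytic joint-extreme envelope
`[0.8·T·0.95, 1.2·T·1.05]` (per case: that envelope over the case count).
Because all triangles are symmetric with mode 1 and independent, the
expected per-case cost equals the base per-case cost exactly.

## Scale-up projection

Per-school cost times the target school count (77 primary public schools in
the Malindi sub-county), assuming constant per-school cost — the four
studied schools and the rest sit under the same county government, so unit
costs are taken as similar; no economies of scale are modelled. Two
deterministic conventions: `results_style` (truncate per-school, then
multiply — $130,515) and `abstract_style` (scale the unrounded total, round
once — $130,573). Uncertainty propagation scales each PSA total draw
(unrounded) by `77/4` and reads the empirical 95% interval of the scaled
draws; this matches the published interval ($119,352–$142,240 within Monte
Carlo noise), which is linear in the unrounded draws rather than a
multiple-of-77 rounding.

## Synthetic data

`simulate_cohort` emulates the screening cascade: each child carries a
latent severity drawn from a categorical prevalence; teachers preselect
impaired children with a given sensitivity and exclude normal-hearing
children with a given specificity; impaired screened children fail the
screen with probability 1 (in the observed program every screen failure was
subsequently diagnosed), normal-hearing children fail at a configurable
false-positive rate defaulting to 0; diagnostic audiometry recovers the
latent severity. Defaults: a 1,000-child pool, triage sensitivity 0.9 (a
documented placeholder — the source literature reports only "high
sensitivity"), specificity 0.9, and a 2.5% pool prevalence split 23:1:2:3:3
across severities, which enriches the screened group to roughly the
observed one-in-five failure rate.

What the generator does *not* emulate: age/sex/school covariate structure,
audiometric thresholds in dB, imperfect diagnostic audiometry, or
between-school cost heterogeneity. Passing tests therefore demonstrate
internal consistency of the pipeline (conservation, monotonicity, parameter
recovery within binomial error), not external validity of the cost
assumptions for other settings.

`perturb_ledger` multiplies each item by one uniform `U(1−r, 1+r)` factor
(r per bucket) applied across *all* scenarios of that item, so
cross-scenario structure (zeros for an absent resident, discounts never
exceeding list price) survives and the perturbed ledger re-validates.

## Numerical and degenerate-input choices

- Half-away-from-zero integer rounding is implemented explicitly (Python's
  built-in `round` is banker's rounding).
- A zero-width triangle or zero half-width collapses draws to the base value
  exactly; an all-zero ledger yields equal lower/base/upper columns.
- Zero screened children, zero identified cases, zero scenario total, and
  empty ledgers raise informative errors rather than returning NaN.
- Tornado ties break alphabetically so ordering is total and reproducible.
- Report bundles embed the config hash and seed and contain no timestamps;
  identical configurations produce byte-identical outputs.

## Known limitations

Single-cycle, provider-perspective costing only: no QALY/DALY
cost-effectiveness, no household costs, no bulk-purchase effects at scale,
no county- or national-level projection. The constant per-school-cost
assumption is inherited from the study design and untested beyond the four
observed schools.
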