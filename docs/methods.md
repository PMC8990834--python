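# Methods

## Coverage model

Adherence is measured as the proportion of days covered (PDC) over a
half-open observation window `[start, end)` of whole calendar days,
anchored at each patient's enrolment: the window is the `window_days`
(default 365) immediately preceding the enrolment date, enrolment day
excluded. A day is covered when at least one controller product's supply
spans it; coverage across products is a union, never a sum.

Each fill contributes `floor(quantity × doses_per_pack / daily_dose)` days
of therapy, with a one-day minimum so that no dispensing is entirely
discarded. Flooring is the conservative convention: a residue smaller than
one day's dose is not counted, and residues are not pooled across fills —
each fill's whole-day content is fixed at dispensing. Within one product,
intervals are swept in date order with the refill-overlap adjustment: an
interval starts at `max(supply_date, previous interval end)` and runs for
its full duration, so early refills are pushed forward intact (full
stockpile carryover). Stockpiles never chain across products.

Boundary choices, made where the convention is genuinely open:

* fills dated before the window contribute nothing (no lead-in coverage —
  only a 12-month history exists per patient); coverage running past the
  window end is truncated, and the truncation is flagged in the per-patient
  audit table;
* the denominator is always the full window length, never shortened to the
  first fill;
* PDC ≥ 80% is adherent, with the boundary inclusive (80.0 counts, 79.99
  does not).

The engine's correctness oracle is a brute-force day-grid simulation: bank
each fill's whole-day content as per-product stock on its supply date, then
spend one day of stock per product per day; a day is covered if any product
held stock. This is exactly equivalent to the interval sweep (property- and
acceptance-tested on randomized patients), and on instances where the pack
content divides evenly by the daily dose it coincides with a dose-level
stock simulation as well. A dose-level simulation that pooled sub-daily
residues across fills would occasionally credit an extra day relative to
per-fill flooring; the per-fill convention is the one implemented, for the
reason above.

## Dose resolution

Pharmacy instructions are parsed against a small fixed grammar —
`<n>[-<m>] <unit> <frequency>` with units puff/inhalation/tablet/dose and
frequencies once/twice/three times/four times daily, mane, nocte, bd, tds,
qid, every morning, every night — and a dose range contributes its mean
("1-2 puffs twice daily" → 3 units/day). Anything else is an explicit parse
failure carrying the raw text; unparseable non-empty instructions are
treated as absent and logged, never silently defaulted.

Every event then receives exactly one regimen by the fallback chain:
its own parsed instruction (*prescribed*), else the most recent earlier
parseable instruction for the same patient **and same product code**
(*carried-forward*), else the product's standard daily dose (*standard*).
Carry-forward never reaches backward in time and never crosses product
codes — dose instructions are strength-specific, so a strength switch
restarts the chain (an ATC-level carry could be added as a config extension
but is deliberately not the default). Same-day ties resolve to the later
event in input order, deterministically. Doses are abstract units/day; no
mass conversion is attempted because PDC only needs doses-per-day against
doses-per-pack.

## Record linkage and pharmacy-use classification

Claims and pharmacy events are matched per patient, greedily and
one-to-one, on exact `(product_code, supply_date, quantity)`. Matching runs
in offset-major passes when a ±k-day tolerance is configured (default 0):
all exact-date pairs form first, so a tolerant match can never steal a
partner from an exact one. Quantity can be dropped from the key by config;
both behaviours are preserved because the original matching rule ("medication
and date collected") leaves it open.

A patient is a **multiple-pharmacy user** iff at least one claims event has
no pharmacy twin; otherwise single. Pharmacy events with no claims twin
(e.g. private, non-subsidized dispensing) do **not** trigger the multiple
class — claims are defined as the complete record for subsidized items —
and are excluded from the combined stream but retained for the
pharmacy-only PDC, with a warning. Patients with zero controller events in
both streams are excluded from adherence analysis and reported separately.

The combined stream contains exactly one event per claims event: matched
events inherit the pharmacy instruction, unmatched ones carry none and flow
through the fallback chain downstream. When every claims event is matched
and no pharmacy-only events exist, the combined stream is event-wise
identical to the pharmacy stream, which forces combined PDC = pharmacy PDC
exactly — the single-pharmacy identity that the test suite checks
bit-for-bit.

## Statistics

Summaries are sample mean/SD (ddof 1) and median/IQR with
linear-interpolation quartiles. Paired comparisons use the paired t-test on
within-patient differences with a 95% t-interval; the rank companion is the
Wilcoxon signed-rank test by default, with a rank-sum-on-differences switch
for compatibility with reports that label the paired companion "WRS".
Unpaired comparisons default to Welch's unequal-variance t (pooled-variance
Student by flag) plus a Mann-Whitney rank-sum p. Degenerate inputs
(zero-variance differences or groups) are returned with a flag, a point CI,
and p = 1 or 0 by direction rather than NaNs. No multiple-testing
correction is applied; report tables carry a note saying so.

Absolute standardized effect sizes for baseline characteristics:
continuous `|m₁−m₂| / √((s₁²+s₂²)/2)`; binary, the standardized difference
of proportions; k-level categorical, the Mahalanobis-type multivariate
standardized difference over the first k−1 level proportions (which reduces
exactly to the binary formula at k = 2 — cross-checked in tests). The
statistic is not bounded by 1; values above 1 are reported as computed and
flagged rather than capped. Zero pooled variance with unequal means yields
NaN with an `undefined` flag.

Calibration is verified by simulation: under a true null the paired-t and
signed-rank p-values are uniform (Kolmogorov–Smirnov check over 2,000
replicates of 40 pairs) and the 95% CI covers the true difference at the
nominal rate within Monte-Carlo error.

## Synthetic cohort generator

The generator emulates the structure of a linked claims/pharmacy asthma
study, not any particular cohort's numbers. Per patient:

* a refill propensity θ ~ Beta(α, β) (default Beta(2, 2)); refill gaps
  beyond supply exhaustion are `floor((1−θ) × Geometric(1/45 days))`, so
  θ → 1 refills on time and θ → 0 leaves long gaps;
* 1–2 controller products from the catalog (40% chance of a second); each
  product's true daily dose is the standard dose times a multiplier from
  {0.5, 1, 2} with default probabilities {0.15, 0.55, 0.30} — mass tilted
  to m ≥ 1 so that, in aggregate, the standard-dose assumption
  overestimates coverage (the direction reported for real cohorts).
  A multiplier that would produce a sub-unit daily dose (inexpressible as
  an instruction) is clamped to 1;
* every fill enters the claims stream; 33% of patients are multiple-pharmacy
  users whose fills are each unobserved by the study pharmacy with
  probability 0.5, with at least one unobserved fill forced so the class is
  identifiable by exact matching. If the unobserved-fill probability is set
  to 0 the cohort is generated, and labelled, all-single (the class would
  otherwise be unidentifiable);
* instructions encoding the true dose (range form 20% of the time, e.g.
  "1-2 puffs twice daily" for 3/day) attach to pharmacy events and are
  omitted with probability 0.1; optional uniform date jitter on pharmacy
  events degrades exact-date linkage for noise experiments;
* an optional correlation parameter couples the routing class to θ
  (default 0; positive values make multiple users the more adherent ones,
  the direction observed in the emulated setting).

Defaults (n = 289 patients, enrolments spread over a 7-month study-like
intake, 365-day windows) were fixed once from these structural
considerations. The realized mean PDC band is higher than real asthma
cohorts report, because the bundled catalog contains long-duration devices
(a 200-dose inhaler at 2 doses/day lasts 100 days) and the generator omits
several real-world depressors of adherence — primary non-collection,
treatment switching and discontinuation, seasonal use, quantity limits. A
passing directional test therefore shows the *ordering and mechanism*
(pharmacy < combined ≤ claims for multiple users; dose-multiplier sign law;
exact single-pharmacy identity), not that real cohorts have these PDC
levels.

Ground truth records each patient's true class, true daily doses, true
covered-day set (with true doses, all fills), and the PDC the claims regime
yields on the complete pre-split stream. Recovery checks assert: noise-free
classification accuracy is 100%; the pipeline's claims-regime PDC equals
truth exactly; pharmacy-only PDC is biased downward for multiple users; and
the dose-multiplier law holds per patient in its monotone form — m > 1 ⇒
combined ≤ claims, m = 1 ⇒ equal, m < 1 ⇒ combined ≥ claims, with strict
inequality whenever coverage does not saturate the window tail. The strict
form cannot hold universally: a fully adherent patient with zero gaps
covers `[first fill, window end)` under both regimes, so the PDCs tie even
at m = 2; tests assert the weak law for every patient plus strictness for
the majority.

## Problem sizes

The test suite and acceptance script use sizes chosen to make the checks
statistically meaningful while staying quick on one CPU: 1,000 randomized
patients for the oracle comparison, 500 patients for the directional
cohort, 150–200 for recovery and identity checks, 2,000 replicates for
p-value calibration. The full suite runs in well under a minute.

## Known limitations

* The dose grammar is deliberately small; PRN ("when required") regimens
  and free-text beyond the grammar are treated as absent doses, which in
  real pharmacy exports would shift more events to carried-forward or
  standard provenance.
* No modelling of dose titration within a product, switching-aware
  persistence, or MPR-style alternatives.
* The bundled catalog's standard daily doses are illustrative placeholders
  in the role of guideline minimum effective adult doses; analyses of real
  data must supply their own catalog.
* Linkage is deterministic key matching, not probabilistic record linkage;
  with date jitter and zero tolerance, multiple-use classification is
  deliberately allowed to degrade (that behaviour is itself under test).
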