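# Methods

This note documents the analytical model the package implements, the
synthetic data-generating process used to validate it, the numerical
choices, and the design decisions taken where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The audit model

The unit of analysis is the *episode*: a pre-order serum value, an optional
repletion order, and an optional follow-up value, all of the same
electrolyte within the same ICU stay.

**Linkage rule.** Each repletion order is anchored to the latest
same-electrolyte draw charted at or before the order and at most
`window_minutes` (default 1440) earlier. All other qualifying draws in
that window are *ignored* — they were superseded by a fresher value before
anyone acted. Orders are processed greedily in time order and an order
consumes its window's draws, so overlapping windows never assign a draw
twice. Draws left unconsumed with no order in their following window are
*no-repletion* (NR) episodes. This yields a partition: every draw is
exactly one of index lab, ignored lab, or NR episode (a fourth "orphan"
bucket — unconsumed draws that *do* have an order in their following
window — is provably empty under greedy assignment, but is still emitted
and checked so the conservation invariant is observable, not assumed).
The follow-up is the earliest draw strictly after the order within the
window; "strictly after" prevents a draw charted at the order minute from
serving as both pre and post, while a draw may legitimately be the
follow-up of one episode and the index of a later one.

**Boundary and tie conventions.** A draw at exactly the order time counts
as preceding (charting granularity makes exact ties common). Simultaneous
candidate draws tie-break to the later charttime, then to the larger input
sequence number; consequently output is independent of input row order
except for distinct values charted in the same stay, electrolyte and
minute, which are observationally interchangeable anyway.

**Classification.** Values are labelled below/within/above a per-electrolyte
`ReferenceRange` with configurable bound inclusivity (inclusive by
default). Ranges are explicit arguments throughout: they are an
institutional convention and the audit's headline percentages depend on
them. Physiologic error bounds (K [2, 7] mEq/L, Mg [1, 5], phosphate
[0.5, 5] mg/dL) remove entry errors *strictly* outside the bounds —
boundary values are retained — at event level, while diagnosis exclusions
act at stay level on the first (`seq_num = 1`) diagnosis only.

**Statistics.** Group comparisons use the pooled-variance two-sample
Student's *t* (df = n₁+n₂−2, two-sided p) and Cohen's d with the pooled-SD
denominator. Pre/post effectiveness defaults to the *unpaired* comparison
of the pre and post distributions — the printed form group summaries take —
with a `paired=True` option computing d on within-episode differences;
which convention an external audit used is generally not recoverable from
group-level summaries, so both are exposed. The regression is OLS
(delegated to statsmodels; validated against a normal-equations oracle to
1e-8) with the conventional summary layout and significance stars at
0.1/0.05/0.01. The default outcome is the post-repletion serum level with
the pre level among the predictors; a 0/1 "decision to replace" outcome
can be fitted as a linear probability model through the same surface. A
non-canonical forward-addition / backward-subtraction p-value screening is
available behind an explicit `stepwise=` flag and is not used by default.
Threshold heterogeneity is a one-way fixed-effects ANOVA
(df = (g−1, N−g)); groups with n < 2 are excluded with a warning. No
multiple-testing correction is applied — a deliberate choice to match the
flat two-sided 0.05 convention of the audits this tooling mirrors.

## Synthetic data-generating process

The generator emits MIMIC-shaped tables whose pipeline output is exactly
predictable, which is what makes end-to-end validation possible.

Per stay and electrolyte, *draw clusters* sit on days spaced
`slot_spacing_hours` (default 96 h) apart, at clock hours drawn from a
two-component circadian mixture (defaults: 06:00 hour with weight 0.7,
18:00 with 0.3, SD 1.5 h, each peak centered mid-hour so its histogram bin
is unambiguous). The serum value is truncated-normal inside the
physiologic bounds; a repletion fires with probability
`base · σ((θ − v)/s)` — a fuzzy threshold, not a step — at the draw time
plus a lognormal latency truncated at the window. With probability
`scenario_mix` an extra non-triggering draw precedes the index draw by
1–6 h (an ML→1R episode); a follow-up draw always occurs after the order
(truncated lognormal delay) with value `v + δ + ε`, ε truncated so the
value stays physiologic. Planted minors, excluded first diagnoses and
out-of-bounds error values are added in exactly known counts
(deterministic rounding of the configured fractions).

Default per-electrolyte settings (native units):

| parameter | K | Mg | PO₄ | rationale |
|---|---|---|---|---|
| value mean ± SD | 4.0 ± 0.45 mEq/L | 3.0 ± 0.45 mg/dL | 3.0 ± 0.55 mg/dL | centred in the nominal range |
| rule base, θ, s | 0.11, 3.7, 0.3 | 0.50, 2.5, 0.3 | 0.85, 2.5, 0.3 | θ at the lower bound; fractions land near the few-percent / ~10 % / ~17 % repletion shares typical of ICU audits |
| post shift δ | 0.32·SD | 1.08·SD | 0.87·SD | small/large/large effect-size bands |
| latency log-mean (σ=0.9) | 4.976 | 5.374 | 5.424 | untruncated means ≈ 217/323/340 min |
| follow-up log-mean | 5.690 | 6.061 | 5.936 | ≈ 443/643/567 min |

These are demonstration defaults chosen once, not fitted claims about any
particular dataset.

**Why clusters are isolated.** With 96-h spacing (validated at parameter
construction: spacing must exceed two windows plus the extra-draw lead
plus a day of clock jitter), no 24-h window can span two clusters. Then,
by construction: every extra draw is consumed as an ignored lab; every
follow-up draw re-enters the pool as an NR episode (clinically sensible —
a follow-up is just another lab order that triggered nothing); and every
untriggered primary is NR. Every `PlantedTruth` expectation becomes a 1-D
quadrature over the value density f(v) (trapezoid rule, 4001 points,
~1e-8):

* per-cluster trigger probability `p̄ = ∫ f(v)·base·σ((θ−v)/s) dv`;
* the *episode-level* repletion fraction the pipeline measures is
  `p̄/(1+p̄)`, because each fired cluster contributes one repletion episode
  *and* one follow-up NR episode;
* repletion-group cell proportions integrate `f(v)p(v)/p̄` over the label
  regions; the NR group is the mixture of untriggered primaries (weight
  1−p̄) and follow-up values (weight p̄), the latter via the truncated-noise
  CDF;
* expected d is `(μ_post − μ_pre)/√((σ²_pre + σ²_post)/2)` with conditional
  moments from the same quadrature (note this is *not* δ/SD: the logistic
  rule selects low values, shrinking the conditional SD, and the follow-up
  noise adds variance);
* latency expectations are truncated-lognormal means in closed form; the
  ML→1R share is `scenario_mix · F(w−360)/F(w)` because extras are only
  planted when the latency leaves room for their lead inside the window.

Residual approximations are deliberate and small: times are rounded to
minutes (sub-minute effects ≪ any sampling SE), and with δ = 0 the
bounds-truncation of the follow-up noise leaves an O(1e-4) asymmetry in
expected d.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: inter-analyte physiology (creatinine–potassium
coupling, co-repletion), dose–response, repeated orders inside one window,
CareVue/Metavision provenance quirks, informative missingness, and draw
schedules denser than one cluster per four days. The generator validates
the *pipeline arithmetic*, not clinical realism of any single stay.

## Numerical and interface choices

* Timestamps are timezone-naive at minute resolution; all arithmetic is in
  minutes. De-identified ICU data preserve time-of-day and differences,
  not calendar truth, so clock hour is read directly from the stored time.
* Unit labels (mEq/L vs mg/dL) are carried, never converted; silent
  conversion would corrupt range classification.
* Printed percentages use decimal half-up rounding to 2 places
  (`round_half_up`); all frames carry full precision.
* ICD-9 exclusion sets ship as editable prefix lists (one named set per
  condition: PRBC transfusion, rhabdomyolysis, parathyroid disease,
  sarcoid, CKD, AKI, ESRD, CAD, CHF, atrial fibrillation, nutritional
  deficiency, paralysis, dialysis) with small sensible defaults; published
  audits rarely print their exact lists, so these are configuration, not
  ground truth. Dialysis exclusion is applied stay-level (whether it
  should be time-window-level is ambiguous in the source conventions; the
  stay-level reading is the conservative one and is flagged here).
* Degenerate inputs: zero pooled SD yields d = 0 for equal means and a
  signed-infinity sentinel otherwise; empty groups produce NaN/undefined
  results, never silent zeros; a constant outcome defines R² = 0;
  rank-deficient designs are hard errors naming the collinear columns.
* The report bundle (CSV outputs) is byte-identical across reruns on
  identical inputs; the run log carries wall-clock ISO-8601 timestamps and
  is excluded from that guarantee.
* Repletion orders with no qualifying preceding draw go to an explicit
  *unanchored* side list — how an upstream audit handled such orders is
  typically unstated, so they are surfaced rather than dropped or forced
  into an episode. Combination products (e.g. potassium phosphate) are
  expanded at ingestion into one order per constituent electrolyte;
  cross-electrolyte anchoring is otherwise off by default.

## Problem sizes

The acceptance suite uses 50 replicates of 5000 stays (≈ 45 000 draw
clusters each) for planted-truth recovery — enough for three-standard-error
checks on every per-electrolyte quantity, including the rare potassium
repletions — and ≥ 1000 random instances of up to 300 events for
brute-force matcher equivalence. `scripts/acceptance.py` measures its
synthetic quantities on one 5000-stay cohort.

## Known limitations

* The magnesium nominal range printed by the source database (2.5–4.5
  mg/dL) is inconsistent with published magnesium cell means near 2.0; the
  package does not guess a "true" range — reproducing such splits requires
  explicitly configured ranges (see `datasets.published_reference_ranges`,
  which documents the reconstruction interval it uses).
* Attrition counts can be read as stays or events depending on the rule;
  the log records both levels explicitly rather than collapsing them.
* The linear probability option for a binary replace/not outcome inherits
  the usual LPM caveats (heteroscedastic errors, predictions outside
  [0, 1]).
* Latency summaries report mean, SD and median; latency distributions are
  right-skewed, so means alone (the commonly printed form) overstate the
  typical delay.
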