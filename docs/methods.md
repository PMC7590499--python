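# Methods

## Problem and scope

Verbal autopsy (VA) infers a cause of death (CoD) from a structured
interview (or record extraction) about the circumstances of a death, in
settings where medical certification is unavailable. `vaval` implements
the computational core of a validation of an InterVA-style probabilistic
VA coder against a gold standard (the complete diagnostic autopsy, CDA):
the coder itself, the individual-level and population-level agreement
metrics, and a resampling design that evaluates those metrics across many
cause compositions. The CDA procedure itself, ethics workflow and the
authentic InterVA probbase contents are out of scope; the engine is
probbase-agnostic.

## The coder

For a death with indicator responses in {yes, no, not recorded} and a
probbase (prior `P0(c)` over K substantive causes, conditionals
`P(i | c)` for each indicator `i`), the posterior is

    P(c | data) ∝ P0(c) · ∏_{i answered yes} P(i | c),

under conditional independence of indicators given the cause. Only
affirmative responses enter the product; "no" and "not recorded"
contribute nothing. This mirrors the cited model family and makes
structurally unavailable indicators well defined. Numerical choices:

* accumulation in the log domain (no underflow for long indicator
  vectors); a direct-product oracle confirms agreement to 1e-9 on small
  instances;
* conditionals clamped to [1e-6, 1 − 1e-6] at load so sparse probbases
  cannot annihilate a cause;
* exact posterior ties broken by dictionary order by default
  (determinism); `tie_break="random"` (seeded) is available and is used
  by the calibration suite, where collapsing a flat posterior onto the
  first cause would bias chance-level estimates;
* prevalence settings (malaria/HIV levels high / low / very_low with
  multipliers 1 / 0.1 / 0.01) rescale the priors of tagged causes and
  renormalise — prevalence is prior information about cause frequency,
  so conditionals are untouched.

Reporting: causes are ranked by posterior; the top cause is reported only
if its posterior reaches `top_threshold` (default 0.4), each subsequent
cause only if it reaches `relative_threshold` (default 0.5) times the top
posterior, up to three causes. Unreported mass is "non-conclusive". The
original tool's internal cutoffs are not published; these defaults
reproduce the qualitative output shape (most deaths a single cause, some
two, a few non-conclusive) and are configuration-exposed, with no claim
of equality to the original.

## Individual-level metrics

Agreement uses the coder's *top* cause against the gold cause; an empty
report counts as the non-conclusive category, which is first-class in the
confusion matrix. Per cause `j`: TP/TN/FP/FN one-vs-rest counts, then
sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN), each ×100. Fractions are carried at full double precision;
integer display values use round-half-to-even, which is the rounding rule
consistent with the published tables this package reproduces (e.g. 62.5 →
62, 87.5 → 88). Zero denominators display as N/A.

Cohen's kappa is computed once on the observed cross-tabulation
(`(p_o − p_e)/(1 − p_e)`); it is not medianised over resampling draws.
Chance-corrected concordance (CCC) per cause rescales sensitivity so
random guessing among K causes scores 0:
`(sens − 1/K)/(1 − 1/K)`, with K the number of substantive causes in the
group's dictionary. Overall CCC is the unweighted mean over substantive
causes with at least one gold death (the metric family's standard
definition; a config-free deliberate choice). Second-cause agreement is
summarised separately (counts and mean likelihood) and never enters the
confusion counts.

## Population-level metrics

Gold-standard CSMFs are simple fractions (one certain cause per death).
Coder CSMFs use partial-likelihood weighting: each reported cause is
credited with its likelihood, and per-death residual mass accrues to
non-conclusive. By default only the first two reported causes are
credited (`max_causes_used = 2`, matching the source analysis), with the
option to use all three.

CSMF accuracy:

    CSMFA = 1 − Σ_j |est_j − true_j| / (2 · (1 − min_j true_j)),

equal to 1 iff the compositions coincide; the denominator is the worst
possible total misallocation given the truth, so the value lies in
[0, 1] (tiny negative rounding residues are clamped). The
chance-corrected version is `(CSMFA − b)/(1 − b)` where `b` is the
random-allocation baseline: the median CSMFA obtained when the truth is
a symmetric Dirichlet(1) composition and each of n deaths is assigned a
uniformly random cause. The analytic constant 1 − 1/e ≈ 0.632 is
available as an alternative baseline; it is the large-K limit of that
median, and for small K the empirical median is materially higher
(≈ 0.67 at K = 2–4), which is why the empirical baseline is the default.

## Dirichlet resampling design

To decouple the metrics from the one cause composition the cohort
happens to have, 500 compositions per study group are drawn from the
uninformative symmetric Dirichlet (alpha = 1, configurable). For each
draw the cohort is resampled with replacement: cause counts from a
multinomial over the drawn composition, records within a cause drawn
from that cause's observed records. Records and coder outputs are
resampled jointly (the coder is deterministic per death). CCC, CSMFA and
CCCSMFA are recomputed per draw and summarised by the median; kappa and
the per-cause confusion table are computed once on the observed cohort,
whose integer counts are raw-data quantities.

Per draw, the CSMF estimate is scored against the *realised* gold
composition of the resampled cohort — so a perfect coder scores exactly
1 on every draw — while the denominator's `min` term uses the drawn
continuous composition, which is never degenerate even when a small
resampled cohort realises a degenerate count vector. Compositions are
drawn over the causes actually observed in the cohort (a positive-weight
cause with no records to resample from would otherwise force a silent
renormalisation on every draw; the renormalisation path exists and
warns). One global seed spawns per-draw substreams via
`numpy.random.SeedSequence`, so results are reproducible bit-for-bit and
independent of execution order.

## Synthetic cohorts

No individual records of the motivating study are publicly available, so
the generator emulates their structure: five groups of 18/41/54/91/112
deaths; per-group true compositions defaulting to the study's published
gold-standard CSMFs; 245 indicators, 43 of which are set to "not
recorded" for *every* record through a single seeded mask (missingness
came from fields absent in clinical records — structural, not
per-patient; 24 of the 43 carry a secondary-question flag that is
behaviourally inert). Deaths of infectious origin also receive an
infection sub-category drawn from the study's published sub-category
distribution. The probbase generator gives each cause a private block of
indicators with P(yes|cause) = 0.05 + 0.9·s against a 0.05 background
and a uniform prior; `s` is the signal strength.

What the generator does **not** emulate: symptom co-occurrence beyond
cause-conditional independence (the engine assumes independence, so a
correlated generator would test a different model), overlap between
cause profiles, and the misclassification level of the real study — with
private indicator blocks the Bayes classifier is near-perfect for any
moderate `s`, so passing tests demonstrate correctness of the machinery,
not field performance of VA. Realistic error levels are injected by the
misclassification simulator, which draws a top cause from an explicit
row-stochastic gold-to-predicted kernel and dresses it with likelihood
noise (first cause ≈ 0.90; with probability 0.10 a second cause ≈ 0.38;
the two means describe disjoint subsets of deaths — single- versus
two-cause reports — so they do not sum below 1 on one death; spreads are
0.05, truncated to valid mass). About one death in ten receiving a
second cause and those likelihood centres match the published output
shape of the study's coder.

## Calibration (parameter-recovery) suite

The suite generates a 500-death, 5-cause cohort with uniform truth at
signal strengths s ∈ {0, 0.5, 1}, codes it with the engine, classifies
by posterior argmax with seeded random tie-breaking, and validates
across 200 draws. It asserts that median CCC, kappa and median CSMFA
rise with s (tolerance 0.02, since strong-signal runs saturate at 1);
that s = 0 sits at chance (|median CCC| < 0.05, |median CCCSMFA| <
0.10); and that s = 1 reaches ≥ 0.9 on all three. Population metrics in
the suite use hard (likelihood-1) top-cause assignments: both chance
corrections are defined against hard random allocation, so the
zero-signal run must *be* random allocation for the chance levels to be
exact; partial-likelihood weighting is exercised by its own tests. A
single 500-death cohort, rather than the study's group sizes, keeps the
chance-level medians within the suite's own tolerances (an 18-death
group's median CCC has sampling noise far above ±0.05).

## Infection-subset report

The pooled infection-level table filters deaths whose gold broad
category is infectious and scores their sub-categories (8 classes, plus
"non-infectious" and "non-conclusive" as terminal prediction classes).
The broad-category coder cannot resolve sub-categories; on synthetic
runs a predicted-infectious death therefore receives a seeded uniform
draw over the eight classes — a synthetic stand-in representing
"infectious, sub-type uninformed" — while non-infectious and
non-conclusive top causes carry through as such. Confusion counts at
this level are meaningful for pipeline-shape and plumbing tests, not as
a claim about sub-category skill.

## Degenerate inputs and edge rules

* Cause dictionaries must contain `non_conclusive` exactly once, last.
* ICD-10 mapping is longest-prefix, group-scoped; at equal length a
  group-specific row beats an "any" row; unmapped codes raise rather
  than defaulting to non-conclusive. An empty prefix is a per-group
  catch-all (used for residual disease classes). The shipped map is
  illustrative: the motivating study never published its full
  code-to-category table.
* Kappa returns NaN when both axes are degenerate on one category.
* CSMF accuracy raises on a truth concentrated on a single cause
  (denominator zero); the resampling harness cannot produce this case by
  construction.
* A probbase prior is renormalised at construction; a non-positive prior
  sum is rejected.

## Problem sizes and tolerances

Default validation runs use 500 draws per group (seconds on one CPU).
The test suite's stochastic checks use 500-death cohorts, 100–500 draws,
and fixed seeds, with chance-level tolerances of ±0.05 (CCC) and ±0.10
(CCCSMFA) chosen from the Monte-Carlo noise of those sizes; the
random-allocation baseline is estimated with 10,000 draws when compared
against its analytic large-K limit. Writer/reader round-trips are exact
to 12 significant digits on likelihoods.
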