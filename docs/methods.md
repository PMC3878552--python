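# Methods

## The audit model

The unit of observation is a *variable*: one of the four numbers (events
and total in each of two arms) a review extracted for one trial cohort
and one binary outcome.  One review is designated the reference
standard; every other review's analysed dataset is compared against it
variable by variable.  The engine computes only whether values differ;
*why* they differ — outright error versus a defensible selection of
alternative data — is a human judgement supplied as an annotation layer,
and the package deliberately does not try to automate it.  A consistency
checker verifies that the annotation layer is compatible with the
arithmetic (an `identical` label on unequal values, or a `selection`
label on an unreported cell, is reported as an inconsistency).

Difference rates are reported per review and outcome as counts over
4 × (units analysed by that review), with integer percentages rounded
half up (so 2/16 → 13%).  Units the review did not report do not enter
the denominator.

### Comparison policy for multi-timepoint cohorts

One trial cohort in the packaged corpus is reported by two publications
(an index paper with 1-year data and a 13-year follow-up), and reviews
differed in which they analysed.  Two policies are implemented:

* `as_analysed` (default): the review's analysed record is compared
  against the reference's *primary* record (earliest timepoint).  A
  review that analysed the 13-year data therefore shows numerator
  differences classified as selection, and denominator differences from
  transposition as errors.  This is the policy under which the packaged
  corpus reproduces the published difference-rate footers, and it
  matches the audit's framing of "one reference dataset of 24 variables
  per outcome".
* `matched`: compare at the review's own timepoint when the reference
  reported it — useful when the question is pure transcription accuracy
  rather than dataset choice.

### Adjudicated cells

When the review reports a value the reference did not extract at all,
no within-corpus comparison exists; the original audit adjudicated such
cells against the primary trial publications.  The annotation layer
carries that adjudication: on reference-NR cells any of
`identical`/`error`/`selection` is accepted by the checker, with
`identical` meaning "matches the primary publication".  Unannotated
differing (or reference-NR) cells default to `error` with a logged
warning, so missing adjudications are loud rather than silent.

### A note on one published count

For the revision outcome, the published per-study cells imply six
selection-labelled differing variables for the Cochrane review (25%),
while the table footer prints 5/24 = 21% and the accompanying text
prints 25%.  The packaged corpus follows the cells (and hence the text);
the footer's count appears to be an arithmetic slip, and no annotation
assignment can reproduce it without contradicting a genuinely differing
cell.  Similarly, the printed Cochrane revision pooled result (0.40,
0.18–0.89) is reproducible only when the trial whose single extracted
event was a wound revision rather than an implant revision is excluded
from that pooled set; the corpus encodes this as an explicit
`analysis_exclusions` entry with that rationale rather than as a hidden
rule.

## Meta-analysis

Per-study effects are log risk ratios with the standard large-sample
variance `1/a − 1/n₁ + 1/c − 1/n₂`.  Zero-cell policy (`half`, default):
double-zero trials are excluded as uninformative for a ratio measure;
single-zero trials get 0.5 added to both event cells and 1 to both
totals (the convention used by mainstream review software); `none`
excludes any zero-cell study instead.  Pooling is DerSimonian–Laird
inverse-variance random effects; `τ²` is truncated at zero, a single
study pools to itself with `τ² = Q = 0`, and setting `τ² = 0` reduces
the estimator to the fixed-effect inverse-variance mean (a tested
equivalence).  Confidence intervals use the fixed 1.96 normal multiplier
— not a t or Knapp–Hartung adjustment — because the published tables
this reproduces use that convention; p-values are two-sided normal.
The implementation was cross-checked against R `metafor`
(`method="DL"`, `add=1/2`, `to="only0"`), which agrees to ≥4 decimal
places on the packaged datasets; those values are frozen into the test
suite.  The Mantel–Haenszel fixed-effect mode (Greenland–Robins
variance, no continuity correction needed) exists as an independent
cross-check because published tables rarely name their estimator; it is
tested against `statsmodels.stats.contingency_tables.StratifiedTable`.

Impact comparisons judge significance by the 95% CI excluding 1 rather
than by the printed p-values, which are rounded more coarsely.  No
formal test of the difference between two pooled estimates is computed;
the comparison is descriptive, matching the audit design.

## Synthetic corpora

The generator emulates the audited situation: a correct reference
extraction of `n_studies` two-arm trials (arm sizes uniform on a range,
comparator risk uniform on a range, index-arm risk `min(1, RR × risk)`,
binomial events) plus `n_reviews − 1` perturbed copies.  Defaults mirror
the case study's scale: 6 trials, 3 reviews, arm sizes 17–111 (the span
of the audited trials), comparator risks 5–25%, null effect (RR = 1),
and per-study perturbation rates of 10% per type — the order of
magnitude of the audited per-variable rates.  Perturbation types map to
the taxonomy: transposition and percentage-recalculation (on an
off-by-one denominator) are errors; alternative comparator arm,
alternative (shorter, risk-halved — an arbitrary but fixed and
configurable scale) timepoint and per-protocol denominator exclusions
are selections; NR masking removes the study from the review.  A single
seeded stream drives everything in a documented order (trials first,
then reviews in order, within each study the types in a fixed order), so
a config fully determines the corpus.  Perturbations that happen to
reproduce the original value (e.g. transposing equal denominators) are
logged but flagged ineffective and excluded from recall accounting;
annotations are derived only for variables whose stored value actually
differs, which makes the generated corpora checker-consistent by
construction.

What the generator does *not* model: correlated errors across studies
or reviews, reviewer-behaviour effects (double extraction, experience),
continuous outcomes, and heterogeneity in the true effect across trials
(the simulated true RR is common to all studies).  Passing tests
therefore demonstrate that the pipeline detects and propagates typed
single-review perturbations under homogeneous binomial sampling, not
that it captures every failure mode of real extraction work.

## Calibration and test scale

With the default null configuration, the 95% CI coverage of the DL
pooled estimate measured over 500 replicate simulated meta-analyses is
~96–97% (DL slightly overcovers with few, homogeneous studies, a known
property of the estimator); the test band is 95% ± 3 points.  Mean
per-study log RR bias under the null is checked over 200 replicates at
tolerance ±0.05; empirical perturbation frequencies are checked at 300
studies against their configured 20% rates at tolerance ±0.05.  These
problem sizes keep the whole suite fast (a few seconds) while leaving
the Monte-Carlo standard errors well inside the asserted tolerances.
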