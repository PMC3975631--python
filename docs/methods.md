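# Methods

This note records the models, parameter choices and numerical decisions
behind `srnasep`, and what the synthetic-data tests do and do not establish.

## Study design being modelled

Three groups of peripheral-blood small-RNA libraries — non-metastasized
(reference), lymphogen-metastasized, occult-metastasized — with five
patients per group. Three comparisons are made, always against the
reference: each metastasized subtype alone (5 vs 5) and both combined
(10 vs 5). All group labels and sample sizes are configurable; the defaults
encode this 3 × 5 design.

## Read processing

**Adapter model.** A read is kept when the leftmost position is found where
either the full 3' adapter occurs (≤ `max_mismatch` mismatches) or a prefix
of the adapter of length ≥ `min_overlap` runs through the read's 3' end.
Defaults `min_overlap = 7`, `max_mismatch = 1` are conventional small-RNA
trimming settings; no published parameter set exists for this analysis, so
read-level concordance with the original (LifeScope + CLC 5.1) processing is
not claimed. "Shorter than 15 bp" is interpreted as: inserts of exactly
15 nt are kept, 14 nt discarded.

**Annotation.** A tag matches a reference entry if it equals the mature
sequence or differs from it only at the 3' end by up to `end_tolerance = 2`
bases (truncation or ignored extension — the dominant isomiR mode). miRNA
entries outrank ncRNA entries when both match, reflecting the primary
interest in miRNAs; within the winning class, a unique match is required.
Ambiguous tags are excluded rather than fractionally shared: the original
pipeline's resolution rule is unknowable, and exclusion is deterministic.
Feature identity is the reference entry id, so precursor-level duplicates
(e.g. two genomic copies of one mature sequence) stay distinct rows.

**Accounting.** Per sample: total reads; kept/no-adapter/too-short (these
three always sum to the total); annotated reads (= the sample's count-matrix
column sum); total and annotated unique tags. Percentages use total reads,
kept reads and total tags as the respective denominators. Group summaries
report mean, n−1 standard deviation (absent for single-sample groups), min
and max.

## Candidate screen

**Normalization.** CPM over each sample's annotated small-RNA reads. The
source analysis states no normalization, but library sizes vary several-fold
in this kind of data, so some per-library scaling is unavoidable; CPM is the
minimal choice consistent with read-count thresholds.

**Filter.** Mean raw count ≥ 50 in at least one compared group ("at least 50
reads", read as a group-mean condition — the least restrictive reading that
still uses the comparison structure), AND CPM group-mean ratio ≥ 2 or ≤ 1/2,
with a pseudocount of 0.5 added to both means so all-zero features are
well-defined (they yield ratio 1 and are excluded). The filter is applied
per comparison against the reference group. Raising either threshold can
only shrink the filtered set.

**Model.** Firth bias-reduced logistic regression of class membership on
x = log2(CPM + 1), one feature at a time. The penalized log-likelihood adds
½ log det I(β) (Jeffreys prior); estimates stay finite under the complete
separation that is routine at n = 5 + 5. Implementation: Newton iteration on
the Firth-modified score with step-halving on the penalized likelihood;
p-values by the penalized likelihood-ratio test against the slope-0 profile;
95% CIs by inverting that test (profile penalized likelihood, bracketed
expansion + Brent root-finding). Profile fits start the intercept at
logit(ȳ) − slope·x̄: covariates live around 10–15 on the log2-CPM scale,
and a naive start drives all fitted probabilities to 0/1 where the
information matrix is numerically singular. A constant covariate degenerates
to slope 0, odds ratio 1, p = 1. The reported `fold_change` (expression
ratio of CPM means) and `odds_ratio` (per log2-CPM unit) are distinct
quantities and are labelled as such rather than conflated.

**Significance.** p ≤ 0.05 without multiple-testing adjustment, matching the
explicitly exploratory design; `adjust="bh"` is available for users who want
FDR control.

**Calibration.** Unconditionally, the penalized LRT at n = 5 + 5 is slightly
conservative (≈ 3% rejections at nominal 5% over 2000 null fits). Note that
*conditional on passing the ≥ 2-fold filter* the p ≤ 0.05 fraction under a
global null is far higher (≈ 0.64 at dispersion 0.2, still ≈ 0.13 at an
implausible dispersion of 1.0): the filter selects exactly those features
whose observed group separation is large. This is a property of the
filter-then-test design itself, worth knowing when interpreting candidate
counts from small-cohort screens of this shape.

## Pair separation

"Complete discrimination" by a feature pair is a geometric statement, so the
primary decision procedure is exact rather than iterative: the samples'
(x, y) = log2(CPM+1) coordinates are converted to exact rationals (every
float is one) and the two classes' convex hulls are tested for disjointness
with integer-exact orientation predicates (monotone-chain hulls; point-in-
polygon and closed-segment intersection tests; degenerate 1- and 2-point
hulls handled explicitly). Strict separation is required — a sample lying
exactly on the candidate line is a failure, since complete discrimination
admits no boundary ambiguity. Disjointness of the closed hulls is equivalent
to the existence of a strictly separating line.

A large-cost (10⁶) linear soft-margin SVM on standardized coordinates,
declaring separation iff training accuracy is 100%, runs as a cross-check
mirroring common practice; disagreements are counted and logged (none have
been observed in 500-instance random suites). liblinear is used rather than
libsvm, whose solver effectively stalls at this cost on non-separable
inputs; its `random_state` is pinned so output bundles are reproducible.
Reported margins are geometric margins of the near-hard-margin SVM line on
the unstandardized log2-CPM plane. A third, independent check — enumeration
of candidate lines through all point pairs with rational ± perturbations —
backs both in the test suite.

Pairs are drawn per comparison from that comparison's significant candidates
by default (`pool="filtered"` widens to all filter-passing features). Every
unordered pair is evaluated exactly once, in lexicographic order. Because a
subtype's point set is a labelled subset of the combined comparison's, any
pair separating the combined comparison necessarily separates both subtypes;
the tests assert this restriction property on synthetic runs.

## Synthetic-data generator

**Counts.** Per-feature relative abundances are log-normal (log-mean 3.0,
log-sd 1.8 — a wide dynamic range typical of blood small-RNA profiles);
implanted truth features multiply their abundance by the configured fold
change in affected groups (optionally pinned to a target baseline mean
count, since realistic discriminating markers are moderately-to-highly
expressed); abundances are renormalized per group and scaled by per-sample
library sizes (gamma, default mean 10⁵ counts and CV 0.25); counts are
negative-binomial with dispersion 0.2 (variance μ + 0.2 μ², i.e. a
biological CV near the "typical human" 0.4; dispersion 0 gives Poisson).
The absolute 10⁷-read depth of real libraries is deliberately not emulated;
all analyses are depth-scale-free apart from the read-count filter, which
tests exercise at desk-scale library sizes.

With overdispersion, single-library column sums legitimately inherit the
biological noise of the most abundant features (the log-normal tail lets one
feature hold a large library share), so sums can deviate 15–35% from the
configured size even at library-size CV 0; the generator is exact in
expectation, and at dispersion 0 realized sums are within ~2%.

**Reads.** Each counted feature emits its mature sequence, with 3'-end
jitter of up to ±2 nt (uniform; extensions use random bases), followed by
the adapter. Three nuisance classes are added as fractions of each sample's
total: adapter-free junk reads (default 0.25), short-insert reads of
5–14 nt (0.02), and unannotatable random inserts (0.13) — rejection-sampled
so junk genuinely lacks an adapter match and unannotatable inserts genuinely
miss the reference. These defaults put ~73% of reads past trimming and ~82%
of kept reads into the annotated class, the accounting structure of real
blood small-RNA libraries. The *tag*-level annotated fraction is
depth-dependent (annotated tag diversity saturates with depth while
unannotated tags keep accumulating), so its real-data value (~7%) emerges
only at deep libraries with small references, not at desk scale; no test
asserts it. Qualities are constant placeholders (no stage consumes them);
no sequencing-error model, colorspace chemistry, or genome alignment is
simulated. FASTQ is gzipped with a zeroed header timestamp so outputs are
byte-reproducible.

**Truth echo.** The generator returns the implant list and the pairs of
strong (≥ 4-fold), same-group implants expected to separate jointly — an
expectation verified empirically by the tests, not a guarantee.

## Determinism and reporting

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline writes TSV tables plus a summary
and a manifest JSON with no timestamps, so identical inputs and
configuration give byte-identical bundles (the manifest differs only where
paths differ). Display rounding (1 decimal for clinical summaries, integer
percentages for overlaps, half-away-from-zero) is applied only at the
reporting boundary; full precision is carried internally.

## Problem sizes used in validation

The shipped validation battery uses desk-scale designs chosen to keep the
whole suite interactive: 15-sample matrices with 80–200 features for
end-to-end and recovery runs (200 replicates for the recovery rate), 4000
features for the global-null screen, 500 random 15-point instances for the
separability cross-oracle, and ~10⁴–10⁵ reads per sample wherever raw FASTQ
is processed.

## Known limitations

- Trimming/annotation parameters of the original instrument pipeline are
  unpublished; only the documented rules above are implemented.
- Ambiguous-tag exclusion slightly undercounts multi-copy families relative
  to fractional assignment schemes.
- The screen's filter-then-test structure makes conditional null behaviour
  anti-conservative (see Calibration); candidate lists from 5-vs-5 designs
  are exploratory by construction.
- Pair search is exhaustive over pairs only (no triples), reports
  training-set separation only, and makes no generalization claim.
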