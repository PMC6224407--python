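# Methods

This note records the models, conventions and design choices behind
`microdial`, in enough detail to reproduce or contest them.

## Study records and normalisation

A study record is one published microdialysis measurement with 18 fields:
identification (PMID, animal count), biological covariates (strain, sex,
age class, consciousness, anaesthetic and its dose), microdialysis setup
(perfusate, calcium concentration in mM, flow rate in µl/min), intervention
(drug, dose in mg/kg, route), location (brain region, neurochemical) and
outcome (peak time in minutes, peak effect in percent of baseline). The
outcome is strictly positive; 100% means no change from the pre-drug
baseline. Drug, region and transmitter names are trimmed,
whitespace-collapsed and case-folded before any matching, because literature
tables mix trade-name capitalisation and spacing; the original strings are
retained on the records frame (`attrs["original_names"]`) for reporting.
Exact duplicate rows (all 18 fields) are dropped with a warning — they are
double entries, whereas near-duplicates are genuine replicate experiments
and are kept. Missing optional covariates become the `unknown` category and
flow through summaries as such. Fine anatomical names map many-to-one onto
coarse region classes through a plain ontology table; mapping is total by
contract and unmapped names are a hard error listing the offenders.

## Fixed-effect meta-analysis

Replicates are pooled per (drug, dose, region, neurochemical, route) by the
animal-weighted mean x̄ = Σ nᵢxᵢ / Σ nᵢ. The weight is the animal count —
the only robustness measure consistently reported across four decades of
papers — not an inverse-variance weight, because per-study variances are
rarely recoverable. Covariates are deliberately excluded from the grouping
key and analysed separately (one-way ANOVA per covariate, one factor at a
time, no interactions; α = 0.05, no multiple-testing correction,
configurable). Peak times are pooled with the same weights; when studies
report different sampling grids this is a weighted compromise rather than a
mode, which we consider the least surprising choice. Random-effects models
and heterogeneity statistics are out of scope by design.

The jackknife recomputes x̄ leaving each study out and compares direction
classifications (up / down / no-change versus the 100% baseline) of the full
estimate against the leave-one-out estimates in a 2×2 (source × up-vs-not-up)
contingency table, tested by χ² or Fisher exact. When every estimate shares
one direction the table is degenerate and the p-value short-circuits to 1
(no skew). This is one defensible construction of the direction test; the
per-study deviations are reported alongside so a different test can be
applied downstream.

Reproducibility: conditions replicated at identical (drug, neurochemical,
region, dose, route, peak time) are binarised (1 above / 0 below baseline;
values at exactly 100% form a third no-change symbol). A condition counts as
concordant only if all replicates share one symbol. The numeric SD is the
sample SD (n−1) of the bits per condition, averaged per compound, then
summarised across compounds — so a fully concordant compound scores 0 even
when it mixes up- and down-conditions. Exact-baseline replicates are
excluded from the numeric SD (they have no natural bit value) but still
participate in the agreement count.

## Fingerprints

Activity per compound and (region, neurochemical) tuple is the arithmetic
minimum pooled response across doses and peak times. The minimum privileges
decreases (a 60% and a 180% response yield 60%); this literal rule is kept
deliberately, with a maximum-|deviation-from-baseline| alternative behind
the `rule` flag for sensitivity checks. Granularity is per-compound by
default; per (drug, dose) pairing by flag.

The ternary encoding {+1, −1, 0} with absent-means-unmeasured is the
internal representation: it preserves direction and keeps "no change"
distinct from "not measured", which binary encodings conflate. Any binary
view (the up/down bit expansion) is derived from it.

Chemical fingerprints are RDKit hashed Morgan fingerprints, radius 2, 2048
bits. SMILES are desalted (largest fragment), stereo-stripped and
canonicalised before hashing so input dialects collapse to one bit vector;
both strippings are configurable.

## Similarity

All response metrics operate on the shared measured tuple set S of a pair;
pairs with empty S are undefined (NaN) and counted, never scored 0 —
missingness is not dissimilarity. The default metric expands each shared
tuple into an up-bit and a down-bit and applies Jaccard |A∩B|/|A∪B| (the
classic Tanimoto, matching a coefficient whose 0 means "no overlap"); the
Rogers–Tanimoto similarity (matches/(matches+2·mismatches), both-zero
positions counting as matches) and the plain signed-agreement fraction are
selectable, and analyses intended for comparison should report all three,
because the two Tanimoto-named coefficients genuinely differ. A pair whose
shared tuples are all "no change" is identical and scores 1 under the
Jaccard expansion despite the empty bit union.

Intra/inter contrast: compounds without any 3rd-level ATC code are excluded;
a pair is intra if it shares at least one code. Per-class distributions are
emitted for classes with ≥ `min_class_size` (default 4) members. The
distribution comparison is a two-sided two-sample KS test with asymptotic
p-value. Class-exclusion robustness recomputes the medians leaving each ATC
code out (compounds losing their last code drop out) and reports the SD of
the leave-one-out medians.

## Frequency maps and clustering

Up/down fractions count fingerprint signs across compounds per tuple;
`fraction_up = n_up/(n_up+n_down)` ignores no-change entries in the
denominator but reports them in `n_total`. "Majority upregulated" is
`fraction_up > 0.5`, strictly.

Clustering drops compounds observed at fewer than `completeness_min`
(default 50%) of the tuples, imputes surviving missing cells at 100
(baseline — the neutral value; the constant is configurable and recorded in
pipeline metadata) and applies complete-linkage agglomerative clustering
with Euclidean distance to rows and columns (scipy linkage; deterministic
given input order). Dendrogram orders and merge heights are returned as
plain tables for external heat-map tools; no graphics are produced here.

## Target association

The drug × target matrix is a binary file input produced upstream at
probability threshold 0.5; this package never runs the prediction tool.
Columns are first intersected with a brain-expressed gene list. "Responding
at category c" means having ≥ 1 measured tuple under c with sign ≠ 0,
direction ignored (up-only/down-only selectable). The hit percentage of
target g at category c is 100 × |responding ∧ predicted active| /
|responding|. Two denominators are implemented because the aggregation
order is genuinely ambiguous: `category` (default) pools responders at the
category level; `tuple_mean` computes hit% per tuple and averages within the
category. Cells need support ≥ 1 to be reported and are flagged low-support
below 3. Compounds with fingerprints but no prediction row are reported,
not silently dropped. Support summed over categories double-counts drugs
responding in several categories — by construction.

## Mutual information

NMI(X,Y) = I(X;Y)/mean(H(X),H(Y)) with natural-log entropies, clipped to
[0, 1]. Conventions (not forced by theory, so fixed here): two constant
vectors score 1.0; exactly one constant vector scores 0.0. This matches the
arithmetic-mean normalisation of the prevailing library implementations,
against which the test suite cross-checks. Response vectors are the ternary
signs as categories (0 is its own category); drugs lacking a measurement at
a tuple are dropped per pair, and pairs with < 2 remaining drugs are
undefined and excluded from aggregates. Per-label aggregation is the
arithmetic mean of that label's defined pairs; the overall summary is the
median and SD of per-label means (a pooled-pairs mode is available);
rankings use per-label medians with mean-then-name tie-breaks.

## The synthetic generator

The generator emulates the statistical shape of a curated microdialysis
corpus; defaults are the study conditions used throughout the recovery
analyses: 6 ATC-like classes × 5 drugs, an 8 region × 8 transmitter grid,
70% tuple completeness, 10% per-tuple sign-flip noise, 2–4 replicates per
measured condition, 4–12 animals per study, log-normal effect noise
(σ_log = 0.1) around 160% (up) / 70% (down) of baseline, 16 candidate
targets plus 4 non-brain decoys, one planted driver target per transmitter
with activity probabilities π₁ = 0.9 (drug truly modulates the driven
transmitter) versus π₀ = 0.1 (background).

Class prototypes carry transmitter-level sparsity (each class modulates a
transmitter with probability 0.5, at least one per class): "drug modulates
transmitter t" is then a meaningful planted truth, which the driver-recovery
oracles require. Unmodulated measured tuples yield exact-baseline (100%)
records — the no-change symbol. Effects are multiplicative log-normal,
respecting the positivity and right skew of percent-of-baseline data; with
σ_log = 0.1 the probability of noise crossing the baseline (flipping a sign)
is negligible (≈ 10⁻⁶), so measured signs equal planted signs for practical
purposes. Covariates mirror the literature's skew (96% male, 80% adult, 89%
freely moving, 60/30/10 strain split). Missingness is
missing-completely-at-random by default; a biased mode oversamples the
first quarter of transmitters to emulate the monoamine skew of real
corpora. Chemistry: each class gets a scaffold from a built-in toy list and
members receive distinct substituents, making intra-class chemical Tanimoto
exceed inter-class on average. All randomness descends from one seed
through named substreams (dataset / predictions / smiles), so components
are independently reproducible.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: pharmacokinetics and dose–response
shapes (doses exist but share one effect distribution), temporal dialysate
dynamics beyond a single peak time, correlated missingness driven by
publication bias within a transmitter, hierarchical lab effects, and real
chemical series. Recovery results certify the statistical machinery, not
the biology.

## Problem sizes and numerical choices

Recovery analyses run 100 seeds at the default conditions (≈ 4,000 records,
30 drugs, 64 tuples per seed); the pooled-effect calibration uses a
large-replicate variant (6–10 replicates) so per-condition weighted
standard errors are meaningful; the deterministic driver-recovery check
runs at π₁ = 1, π₀ = 0 where recovery must be exact. These sizes were
chosen so the whole suite and the acceptance script each complete in well
under a half hour on one CPU while leaving the multi-seed rates with
comfortable margins. Tolerances: exact arithmetic is asserted to 1e-12
relative; float comparisons of derived statistics use pytest defaults
(1e-6 relative). Ties in activity aggregation (`max_deviation` rule) break
toward the smaller value; ranking ties break by mean then label name;
linkage determinism is inherited from scipy given a fixed row order.

## Known limitations

The jackknife direction test is one reading of an under-specified
procedure; the up/down binarisation discards effect magnitude entirely;
the minimum-activity rule is asymmetric by design and inherited as-is; the
per-label NMI median over all tuples dilutes labels whose information is
spatially concentrated (a per-transmitter driver informs only its own
tuples), which is why planted-driver dominance is assessed as a majority of
the top-5 ranks rather than a sweep of the very top; and annotation-space
comparisons (ATC vs targets) depend strongly on how each space relates to
the response-generating process, so cross-space conclusions from synthetic
data should not be read as statements about real corpora.
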