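# Methods

This note documents the models, conventions and design choices behind
`emofacs`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model

A study configuration has 13 emotion categories (amusement, anger, awe,
contempt, disgust, embarrassment, fear, happiness, interest, pride,
sadness, shame, surprise — this alphabetical order is the contract for
all profile vectors).  Ratings use the unambiguous-Likert convention: a
NO response is encoded as 0 on the same scale as YES intensities 1–4, so
per-category medians over a rater panel are well defined and thresholds
such as "below 2" apply uniformly.  Medians of even-sized samples are
interpolated (midpoint) throughout — rater panels, variant aggregation,
imputation iterations, cut scans — so profiles are continuous in the
data.

FACS codings cover AU1–AU27 (no AU3 exists) with intensities A–E mapped
to 1–5; unilateral codes are dropped on ingest.  AU identifiers above 27
denote head/eye movements uncodable from a static photograph; they are
carried in configuration variants as *dynamic* AUs.  "At least moderate
intensity" means FACS level C, i.e. ≥ 3 on the 1–5 scale.

The packaged registry of hypothesized configurations
(`src/emofacs/data/hypothesized_configurations.yaml`) transcribes the
prototype AU lists published in the basic-emotion literature, with
"with or without" alternatives expanded into explicit variants.  It is
data, not code: pass any file with the same schema to substitute your
own prototypes.  Pride (53+64) and shame (54+64) are entirely dynamic;
amusement and embarrassment include a dynamic AU in every variant; these
four are flagged *simulation required* — reliability is estimated by
imputation and specificity is undefined for them.

## Match scoring

The match score m = 2|A∩B| / (|A|+|B|) is symmetric, 0 for disjoint and
1 for identical non-empty sets, and undefined (an error) when both sets
are empty.  Reliability bands are left-closed: none [0, 0.2), weak
[0.2, 0.4), moderate [0.4, 0.7), high [0.7, 1], so a score of exactly
0.4 is moderate.

A pose is scored against a category by scoring its activated AU set
(optionally filtered to intensity ≥ 3) against every variant and
combining by the median (default; max and min are exposed and are the
liberal choices for the prototype and context-sensitivity hypotheses
respectively).  When several coders coded a pose, the analyzed coding is
the consensus: an AU is present iff a strict majority of coders marked
it, with the rounded median intensity.  Majority consolidation is an
assumption — the consolidation rule used for the original three-coder
codings is not recoverable — and is therefore isolated in one function
(`consolidate_coders`).

Dynamic-AU imputation adds each missing dynamic AU independently with
probability equal to the median AU base rate (median over the 26 codable
AUs of their activation frequency across poses), re-scores the augmented
pose, and reports the median over 1000 seeded iterations.  The
Monte-Carlo median equals the exhaustively enumerated weighted median
whenever the latter is unambiguous; the test suite checks the MC value
against the enumeration's central quantile bracket for up to three
missing AUs.

## Supervised reliability and specificity

Scenarios are assigned to categories by highest median rating, ties
broken by smallest IQR, then by highest pose match score, then (logged
loudly) by fixed category order.  The high-intensity subset keeps
scenarios whose *assigned-category* median is ≥ 3; this reading of
"average median intensity" (per-scenario scalar on the assigned
category) is a documented choice — the alternative, averaging over all
13 categories, is not a per-category intensity.

The Bayesian reliability test compares interval hypotheses about
θ = P(pose matches at m ≥ 0.4): null [0, 0.4) (none or weak), moderate
[0.4, 0.7), high [0.7, 1], each with a uniform prior on θ within the
interval.  Marginal likelihoods are closed-form incomplete-beta
expressions; Bayes factors are reported against the null.  The interval
(rather than point-null) formulation is a design choice; the width-
weighted marginals provably sum to the flat-prior Beta-binomial
evidence, which the tests verify.

Specificity for category *e* is 1 − p̂\_e with p̂\_e = k\_e / n\_e:
n\_e counts poses with m ≥ 0.4 against *e*'s configuration, k\_e those
whose scenario profile has median(*e*) < 2 while some other category's
median exceeds 2.  The thresholds (< 2 target, > 2 other, strict
inequalities) generalize the worked anger/sadness rule to all
categories.  Uncertainty uses the Jeffreys Beta(k+½, n−k+½) posterior:
equal-tailed 95% credibility interval (bounds pinned to 0/1 at k = 0 or
k = n) and a one-tailed posterior probability that θ exceeds the chance
rate 1/9 (one out of nine testable categories; configurable).

The multiverse runner re-executes reliability and specificity over a
full factorial grid of analytic choices (default axes: variant
aggregation median/max/min × intensity filter any/≥ moderate) and
summarizes per-cell medians; cell failures are recorded, never fatal.

## Inductive clustering

Profiles are clustered with scipy's agglomerative linkage.  Candidate
method × metric pairs are scored by cophenetic correlation; geometric
methods (centroid, median, ward) are evaluated only with Euclidean
distances.  Ties (within 1e−9) prefer average linkage — within-cluster
homogeneity over centroid separation — matching the documented
preference for averaging over centroid linkage when both tie.

"Every possible solution" is read as every cut k = 1…n of the single
selected tree, not every partition.  A cut is scored by the median of
within-cluster pairwise pose match scores, pooled across non-singleton
clusters (default) or as a median of per-cluster medians (option);
singletons contribute nothing.  The maximizing k wins, smallest k on
ties.  Cluster characterization builds the common AU set (median
intensity across members ≥ 3, absent = 0), scores it against each
category taking the max over variants with the category's dynamic AUs
assumed active (an upper bound), and counts categories at m ≥ 0.4; a
per-pose-median variant is provided as method 2.

## Synthetic worlds

The generator emulates the study's structure — 604 scenarios, 13
categories, 40 raters per stimulus and condition, 3 coders by default —
with three regimes.

*Rater model*: presence ~ Bernoulli(σ(4·(λ − 0.5))) in the latent
intensity λ ∈ [0, 4]; given presence, the value is λ plus N(0, 0.5)
jitter, rounded and clipped to 1–4.  Panel medians converge to integer
latents as the panel grows (tested at 400 raters).  Scenario latents
have a dominant category at 3–4 plus Poisson(2.8) secondary categories
at 1–2; face latents copy the scenario latent with probability 0.3 and
are otherwise independent with Poisson(0.43) secondaries, so scenario
profiles are more complex than face profiles by construction.  The
face+scenario latent is an explicit convex combination (default weight
0.8 on the scenario), making the headline context ordering a planted
ground truth rather than an assumption.

*Prototype regime*: each scenario's actor poses one of its category's
hypothesized variants with probability `prototype_adherence` (default
0.5), otherwise a 4-AU configuration disjoint from all of that
category's variants, so the fraction of poses with m ≥ 0.4 against the
true category is exactly Binomial(n, p).  The *mixed* regime adds
leakage: with probability `leakage_rate`, an adherent scenario's profile
is re-dominated by another category (target median 1, other 3–4),
planting a known false positive rate.

*Context regime*: clusters get disjoint 5-AU repertoires; a fixed
fraction (1 − `pose_fidelity`, default 0.2) of each cluster's poses —
an exact count per cluster, not an independent coin per pose — have one
repertoire AU swapped for an off-repertoire AU.  This makes the share of
identical-pose pairs within a cluster a design constant (0.8² = 0.64 of
pairs at m = 1), so the cut scan's pooled median is maximized exactly at
the planted k: finer cuts tie at m = 1 and lose the smallest-k
tie-break, and any merge of two of five equal clusters dilutes the
m = 1 atom below half (0.64 · 950/1350 ≈ 0.45).

*Coder model*: intended AUs get intensities 3–5; each coder misses a
present AU and adds a spurious weak AU with probability 0.05 (majority
consolidation then recovers the intended pose almost surely with three
coders).  Recovery tests that assert exact binomial identities set the
coder noise to zero, which is part of their stated conditions.

What the generator does *not* emulate: actor identity effects,
correlated AU co-activation beyond the repertoire structure, cultural
or individual rater biases, free-label or "neutral" responses, and any
image-level process.  Passing recovery tests therefore demonstrate that
the pipeline measures what it claims under its own assumptions, not
that real data satisfy those assumptions.

## Problem sizes and numerical choices

The test suite uses scaled-down but statistically calibrated problem
sizes chosen a priori: 600 poses × 100 replicates for adherence
recovery (boundary distances ≥ 5 binomial SDs, so Bayesian band
selection is near-deterministic); 120 poses × 200 replicates for
leakage recovery, with n = 120 picked because the exact (binomial-sum)
coverage of the equal-tailed Jeffreys interval at θ = 0.1 and 0.48 is
≈ 0.954–0.956 there, comfortably above the 0.93 test floor; 100
scenarios in 5 clusters × 10 seeds for clustering recovery; 60–120
scenarios for the context checks (the variance decomposition requires
≥ 30 stimuli for 26 predictors).  The acceptance script runs smaller
replicate counts of the same designs plus one default-condition study
pass at 208 scenarios × 20 raters.

Numerical conventions worth knowing: marginal likelihoods are clamped
away from exact zero to keep Bayes factors defined; the variance
decomposition refuses rank-deficient designs (condition number check
naming the most collinear columns) and computes semi-partials from t
statistics (sr² = t²(1−R²)/df), which degrades near R² = 1 — near-
perfect fits are a degenerate input.  With adherence exactly 0.5 the
per-category median match score is a knife-edge statistic (half the
scores are 0, half ≥ 0.4), so the default-world "overall median
reliability" is bimodal across seeds; the pooled mean match score is
reported alongside it as the stable summary.

## Known limitations

Exact replication of dataset-level numbers requires the original
deposited data tables; the package consumes them in its documented CSV
dialects but does not ship them.  The registry transcription covers the
main published variant lists, not every "with or without" expansion in
the supplementary literature.  The Bayes-factor construction is an
interval formulation with uniform within-interval priors; other
constructions (point nulls, informative priors) would give different
factors on the same counts.
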