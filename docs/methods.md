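# Methods

## Model and assumptions

`tmepre` assumes a complete, normalized, log2-scale genes × samples
expression matrix with gene symbols as identifiers (probe-to-symbol mapping
and batch correction happen upstream) and a sample table with MSI status in
{MSI, MSI-L, MSS, Unknown}.  Missing expression values are rejected rather
than imputed.

The biological premise is that anti-PD1 response requires (1) CD8+ T-cell
infiltration of the tumor and (2) an infiltrate that is not terminally
exhausted.  Both properties are read from bulk expression through marker
genes: CD8A proxies CD8+ T-cell abundance, and co-expression of the
inhibitory receptors PD1 (*PDCD1*) and TIM3 (*HAVCR2*) marks early terminal
exhaustion — TIM3 being among the first co-inhibitory receptors acquired,
which makes the pair a sensitive flag for the exhausted state.

### Training contrasts

* Infiltration: the CD8A cutoff is the 40th percentile of CD8A *within MSI
  tumors*.  POS = MSI strictly above, NEG = MSS strictly below; MSI-L,
  Unknown, ties, MSI-below and MSS-above samples are all excluded.  The
  percentile is the ceil(p·n)-th order statistic, under which 131 distinct
  MSI values leave exactly 78 strictly above the 40th percentile.
* Exhaustion state: within the infiltration-POS samples, marker medians
  (standard midpoint median) split each receptor.  Both-strictly-below is the
  POS class ("can still respond"), both-strictly-above the NEG class
  ("terminally exhausted"), mixed or tied samples are excluded.  Orienting
  the responsive group as POS makes a *high* TME2 score mean an anti-PD1
  responsive microenvironment, which is the direction every downstream
  decision rule uses.

Values exactly at a cutoff fall in neither group; all comparisons are
strict.  This convention is what reproduces the printed group arithmetic and
is exposed in the API rather than hidden.

### Stability selection

Each round draws a fresh stratified 10-fold partition of POS ∪ NEG (class
proportions preserved within each fold, which prevents empty-class folds for
small balanced contrasts) and designates fold *r* mod 10 of round *r* as the
held-out fold.  A two-sided Welch *t*-test ranks all candidate genes —
ascending *p*, ties broken by larger |t| and then gene identifier, so runs
are fully reproducible — and the top 60 genes of the round are recorded.
Genes appearing in the top 60 in ≥80% of 200 rounds form the signature; CD8A
is removed from candidacy for the infiltration component so the signature
measures the microenvironment program rather than the marker that defined
the groups.

The *t*-test is evaluated **on the held-out fold** by default
(`StabilityParams.test_split="holdout"`).  This choice is deliberate: when
the test is run on the retained 90% instead (`test_split="train"`, also
available), consecutive rounds share almost all their samples, so any gene
associated with the contrast in the full cohort — including pure chance
associations — reappears in every round; measured at a 78-vs-211 contrast
with 1000 null genes, about 25 genes reach selection frequency 1.0 under a
null contrast, and the 80% rule filters nothing.  With the held-out-fold
test, rounds score nearly disjoint subsets, the frequency filter measures
genuine stability, the same null yields zero selections, and strong planted
effects (3 log2 units over unit noise) are still recovered completely.  It
also explains why a top-60 rule can emit a signature much smaller than 60:
only robust genes survive the churn between rounds.

Welch's unequal-variance *t* is used because the contrast groups differ in
size and have no reason to share variance.  Genes with zero variance in both
groups and equal means are assigned *p* = 1 (no evidence) — with differing
means the statistic is ±∞ and *p* = 0.

### Nearest-centroid score and cutoff

Per-gene standardization parameters (mean, SD with ddof = 1) are pooled over
the POS ∪ NEG training samples; class centroids are the standardized group
means.  The score is the difference of Euclidean distances to the two
centroids divided by the number of genes, so scores are comparable across
signatures of different sizes and a higher score always means more
POS-like.  The training cutoff is the minimum POS-sample score:
sensitivity 1 on training data by construction, with the greatest
specificity attainable under that constraint.  The distance metric, pooled
standardization and score normalization are package conventions — the
nearest-centroid functional form is otherwise underdetermined — and the
decision rules consume only score ranks or cutoff comparisons, so these
choices affect little beyond numerical readability.

### Decision rules

Training-platform rule: responder iff TME1 ≥ its cutoff and TME2 ≥ its
cutoff; nonresponders are labeled *insufficient_infiltration* when TME1
fails, else *terminal_exhaustion*.

Cross-platform (validation) rule: trained cutoffs do not transfer across
platforms, so within the new cohort the lowest and highest TME1 quartiles
(same order-statistic convention as the percentile cutoff) and the TME2
median are computed, and a sample is a nonresponder iff its TME1 score is in
the lowest quartile, or in the highest quartile with TME2 strictly below the
cohort median.  All other samples — including the middle TME1 half — default
to responder, since the rule only defines nonresponders.  The quartile/median
reading of "the median was equally split as the cutoffs for each component"
is the package's interpretation of an ambiguous prescription and is exposed
as configuration (`validation_low_quantile`, `validation_high_quantile`).

### Read-outs and evaluation statistics

* CD8-restricted read-out: for purified CD8+ T-cell data the TME2 signature
  is narrowed to genes primarily expressed by CD8+ T cells (default: CCL5,
  CD2, CD48, CD84, FAM78A, HCST, IL21R plus the receptors HAVCR2 and PDCD1 —
  a curated list supplied as configuration, since cell-type attribution is a
  database lookup outside this package).  Centroids and standardization are
  restricted to the intersection with the signature; higher score ⇒
  progenitor-exhausted-like, i.e. anti-PD1 responsive.
* ω (relative range coverage) = subgroup score range / full-cohort score
  range; invariant under jointly applied positive affine transforms.
* Survival: two-group log-rank test and single-covariate Cox proportional-
  hazards fit (Efron tie handling, via lifelines), with monotone-likelihood
  failures reported as an infinite-HR flag rather than an exception.  The
  one-sided log-rank *p* is oriented so that nonresponders dying faster
  gives *p* < 0.5.
* Stouffer combination uses z = Φ⁻¹(1 − p) per cohort and
  p = 1 − Φ(Σz/√k).  Fed the three published validation *p*-values
  (0.056, 0.115, 0.003) it returns 6.9 × 10⁻⁴ ≈ 0.0007; a two-sided reading
  does not reproduce that value, which fixes the convention.
* Reported percentages use half-up rounding to one decimal, matching how
  such tables are conventionally printed (e.g. 30/284 → 10.6, 246/284 →
  86.6, 88/131 → 67.2).

## Synthetic cohorts

The generator emulates exactly the structure the method assumes and nothing
more: background genes are i.i.d. normal in log2 space (per-gene baseline
mean ~ N(7, 2), noise SD 1 by default — typical magnitudes for normalized
microarray data); a latent infiltration state raises CD8A and a planted gene
block by a configurable effect (default 3 log2 units); a latent exhaustion
state, nested strictly within infiltration, raises PDCD1, HAVCR2 and a
second block.  Marker genes carry the same effect as their program, since
the method treats them as proxies of it.  Defaults mirror the training-
cohort composition: 131 MSI / 284 MSS samples, infiltration prevalence 0.6
in MSI (so roughly the 40th CD8A percentile separates the states) and 0.1 in
MSS, half of infiltrated tumors exhausted, 1000 genes with 20 planted per
program.  Survival attachment draws exponential event times whose hazard is
multiplied by a chosen true HR for predicted nonresponders
(baseline hazard 1/365 per day), with independent uniform censoring.  All
randomness flows through NumPy's PCG64 generator, so fixed seeds reproduce
cohorts bit-for-bit across platforms.

What the generator does **not** emulate: gene–gene correlation beyond the
two planted programs, platform or batch effects, probe-level artifacts,
MSI-L/Unknown strata (generated cohorts contain only MSI and MSS), and
continuous (rather than binary) infiltration levels.  Passing tests on these
cohorts therefore demonstrate that the procedures recover the structure they
assume when it is present — planted-gene recovery, correct group
construction, correct orientation of every rule, calibrated test levels —
not that the derived signatures would match those from real tumors.

## Problem sizes and numerical choices

The test suite and the acceptance script run derivations at 50 selection
rounds (the frequency threshold then requires 40/50 rounds) and cohorts of a
few hundred samples and 200–1000 genes; the full 200-round defaults are used
where a single derivation is exercised.  These sizes were chosen so the
whole suite completes in minutes while leaving every statistical check
adequately powered.  Oracle comparisons use absolute tolerances of 1e-10 to
1e-12 for closed-form arithmetic, 2e-3 for grid-search maximizers, and
binomial-band assertions (e.g. type-I error in [0.03, 0.07] at 2000
permutations) for calibration checks.

## Known limitations

* The package derives signatures; it does not ship the published 28- and
  29-gene lists, which are data-dependent outputs of cohorts this package
  does not download.
* The validation rule's quartile/median reading, the nearest-centroid
  conventions and the held-out-fold testing default are documented package
  decisions where the underlying prescriptions are ambiguous; all are
  configurable.
* Cox fitting assumes proportional hazards; the simulator generates
  exponential times that satisfy it, so model misspecification is untested.
* Classification quality on real data depends on platform normalization,
  which the package deliberately leaves to the caller: inputs are expected
  already log2-transformed, including RNA-seq cohorts.
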