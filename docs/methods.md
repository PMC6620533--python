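# Methods

This note records the model and the numerical/design choices behind
`neurofuse`, at the level of detail a user needs to interpret its outputs
and its test results.

## Atlas and feature universes

All matrices are indexed by the 68 cortical regions of the
Desikan–Killiany parcellation in FreeSurfer `aparc` order — the left
hemisphere's 34 regions, then the right's — with aparc+aseg integer codes
(1001–1035 / 2001–2035, corpus callosum excluded). The pairwise feature
universe is the strict upper triangle i < j: 68·67/2 = 2 278 connectivity
features and 2 278 × 8 = 18 224 structural delta features. The lower
triangle carries no extra information (the connectivity matrix is
symmetric, the delta tensor antisymmetric) and the diagonal is excluded
(ρ = 1 and Δ = 0 are constants). Structural features are ordered
slab-major: all (i, j) pairs of feature 1, then feature 2, ….

## Morphometry and the delta tensor

Per-vertex curvature features use the convention that the principal
curvatures are ordered by magnitude (|k₁| ≥ |k₂|) before the folding index
FI = |k₁|·(|k₁|−|k₂|), making FI and ICI nonnegative. Regional averages of
the curvature features are unweighted vertex means (area weighting exists
behind `area_weighted=True` but is off by default); thickness SD is the
sample (n−1) SD. The delta tensor is *signed*,
Δ[i,j,f] = x[i,f] − x[j,f], and both triangles are carried in memory so
region-indexed consumers (maps) need no sign bookkeeping; classifiers and
the screen use only the upper triangle. Its purpose is confound
cancellation: any additive per-subject offset common to all regions drops
out of every pairwise difference exactly (property-tested).

## Connectivity

Functional connectivity is the plain Pearson matrix of the 68 mean region
time courses; no detrending or filtering happens here (temporal
preprocessing belongs upstream). Voxel-to-region assignment in the
optional 4-D extractor is by exact label equality — no partial-volume
weighting, since no interpolation rule is defined for the inputs the
package accepts. A constant (zero-variance) time course makes correlation
undefined; those entries are recorded as 0 with a warning rather than
aborting a cohort run, and the diagonal is forced to exactly 1.

## Local KNN stage

One KNN per scalar feature, k = 7, absolute distance. Local accuracies and
autism probabilities are **out-of-fold** under stratified 4-fold CV with a
fixed seed, identical folds for every feature and both modalities —
training-set (resubstitution) estimates would be optimistic and are
available only behind an explicit `resubstitution=True`. Probabilities are
the fraction of ASD labels among the k neighbours (multiples of 1/k);
probability exactly 0.5 resolves to TD, the conservative default. Exact
distance ties are broken by position in a seeded shuffle of the training
subjects, so reruns are bit-identical.

Implementation: because a scalar KNN needs only ordered neighbours, the
grid evaluator sorts each feature's training values once and resolves each
query inside the 2k-wide window around its insertion point, vectorised
across features. This is exact (oracle-tested against exhaustive search)
and makes the 18 224-feature grid take seconds.

A note on invariances: local results are invariant under *positive affine*
rescaling of a feature (distances scale uniformly), and that is the
invariance the property tests assert. General strictly monotone maps can
change nearest-neighbour sets on a line (an asymmetric stretch can flip
which side's neighbour is closer), so no such invariance is claimed.

## Ranking, prefix scan, fusion

Features are ranked by local accuracy, ties broken lexicographically by
(slab, i, j) for determinism. The prefix scan evaluates ranked prefixes
1..L (default cap 100) with a random forest (Gini impurity) under outer
stratified 4-fold CV; the forest's `n_estimators` ∈ {10, 50, 100, 200} and
`max_depth` ∈ {2, 4, 8, ∞} are chosen by an inner 3-fold grid search on
each training split (the grid is a deliberately small, standard one — only
the two hyperparameters are part of the protocol). Simulations and the
test suite use the single-point grid (100 trees, unbounded depth) where
the inner search is not the object under study. The chosen prefix length
is the *smallest* length attaining the maximum accuracy. Fusion
concatenates the two optimal prefixes and repeats the same evaluation on
the subjects with both modalities present; subjects missing a modality
are retained for their available branch and excluded from fusion.

Metrics come from the pooled out-of-fold confusion table (ASD positive);
AUC is the trapezoidal ROC area of the pooled out-of-fold probabilities —
pooling is more stable than per-fold averaging at n ≈ 200.

Two evaluation modes: `"ranked"` (default) ranks features once on the full
cohort's out-of-fold local accuracies before cross-validating the global
classifier — the two-stage protocol as published, which leaks ranking
information and is therefore optimistic; `"nested"` re-ranks and
re-selects inside every outer training fold (with the fixed-point forest
configuration) for an honest estimate. Both are reported when requested so
the optimism is measured, not guessed.

The classifier comparison applies the identical outer CV to four families
with fixed, documented settings: random forest (100 Gini trees), RBF SVM
(C = 1, AUC from the decision function), Gaussian naive Bayes, and a
one-hidden-layer (32-unit) feed-forward network. All families see the same
fused features; none re-selects its own.

## Severity screen and demographics

The screen correlates each pairwise feature with the ADOS total across
scored subjects; significance is |r| ≥ 0.32 two-sided (at n = 61 this is
p ≈ 0.0119, i.e. the 0.01 operating point). p-values use the exact t
transform t = r√(n−2)/√(1−r²) with n−2 df. No multiple-testing correction
by default — the raw-|r| threshold *is* the protocol — with an optional
Benjamini–Hochberg flag. Region frequency counts each significant feature
toward both of its regions; ties in the ranking break by atlas order.

Demographic tests: χ² on the 2 × 2 sex-by-diagnosis table *without*
continuity correction, and a pooled-variance two-sample t on age. The
moment overload recombines subgroup (count, mean, SD) summaries exactly
(combined SS = Σ[(nᵢ−1)sᵢ² + nᵢ(mᵢ−m)²]), so summary-level and raw-level
computations agree to machine precision.

## Personalized maps

V_f(i) = max over partners j ≠ i of P_F(i, j); V_s(i) additionally maxes
over the 8 slabs. The printed definition of the structural map bounds the
partner index below by i; that asymmetry is treated as a typo and the max
runs over all partners, symmetric with the functional map. With ~500
features per region, the maximum is a high order statistic — map values
near 1 are expected even for TD subjects, and the informative signal is
the *contrast* between regions and groups, not the absolute level. The
schematic export colours a 4 × 17 region grid; cortical-surface rendering
is out of scope.

## Synthetic cohorts

The generator emulates the shape of the study population: 72 ASD
(33 M/39 F) + 113 TD (49 M/64 F), subgroup age means/SDs matching the
published cohort table, 61 ASD subjects with an ADOS total in 1–24, and 7
subjects without usable resting-state data. T = 180 time points reflects
≈ 6 min at TR = 2 s (the acquisition length is stated only approximately
upstream; T is a free parameter).

* **Morphometry**: region × feature baselines are Gaussian around
  FreeSurfer-like levels (A ≈ 2500 mm², V ≈ 6500 mm³, thickness ≈ 2.55 mm,
  curvature indices ≈ 0.02–0.13), fixed by a separate `structure_seed` so
  different cohorts share one "population". A per-subject per-feature
  global offset (SD = 2 × the within-subject noise SD) simulates the
  head-size/scanner confound the delta tensor must cancel — recovery is
  tested end-to-end to be independent of it. Planted ASD shifts are
  specified in SD units *of the pairwise delta feature* (region-space
  shift = shift·√2·σ), the scale the classifier sees; the defaults plant
  five 1.5-SD shifts at spread-out (region, slab) elements.
* **Connectivity**: time courses are zero-mean multivariate Gaussian draws
  from a low-rank (rank-6) plus diagonal base correlation structure; ASD
  deltas (default five disjoint edges at +0.4) are added in correlation
  space and kept *exact*, guarded by a positive-definiteness check
  (smallest eigenvalue > 1e-6) instead of a nearest-PSD projection, so
  planted ground truth is not distorted.
* **Severity**: an affine combination of the subject's realized
  planted-effect deviations plus Gaussian noise, rounded and clipped into
  [1, 24]. Structural deviations are offset-free (the global confound is
  subtracted), so severity tracks the same region-specific signal the
  delta features carry. Default drivers (two shifts + one edge at weight
  1, noise 0.6) give each driving pairwise feature a designed severity
  correlation ≈ 0.39; a single driver at the same noise gives ≈ 0.6.

What the generator does **not** emulate: spatial autocorrelation of
morphometric noise, hemodynamics/autocorrelated BOLD noise, motion
artefacts, site effects, or label noise. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
effects under clean conditions — not expected performance on real cohorts,
where the published accuracies (≈ 0.74–0.81) are far below what the strong
planted defaults produce here.

## Problem sizes and known limitations

Simulation tests use 200-subject cohorts (the recovery condition), a
40-subject fast cohort for pipeline smoke tests, prefix scans capped at
10–40 features, and the single-point forest grid; the acceptance script
runs the full pipeline on one 185-subject cohort with a 40-length scan.

One structural limitation is worth stating plainly: a planted structural
element lives at (region, slab) level and therefore spawns 67 correlated
delta features of near-identical strength. Rankings consequently recover
planted *regions* reliably within the top ~100 features (the prefix-scan
range), but the top-20 of the global ranking is typically crowded by the
strongest two or three planted regions, so "every planted element in the
top 20" is not a stable property of region-level planting — exact planted
connectivity edges, by contrast, rank in the top 5 essentially always.
The recovery suite measures and reports both.
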