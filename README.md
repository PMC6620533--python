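# neurofuse

Two-stage multimodal MRI fusion classification for autism computer-aided
diagnosis, with personalized per-region probability maps and an ADOS
severity-correlation screen.

## The problem

Autism spectrum disorder (ASD) diagnosis from MRI is usually posed as a
single whole-brain decision. This package implements a *localized*
alternative: every pairwise brain feature gets its own tiny classifier, and
those local decisions are (a) aggregated into a global diagnosis and (b)
kept as a per-region map of where an individual's brain looks most
autism-like. It is aimed at researchers working with cohort-level
structural + resting-state MRI feature tables (the kind FreeSurfer and FSL
pipelines emit) who want a tested, reproducible implementation of the
two-stage local/global protocol — including a synthetic-cohort generator,
because the cohorts this method was developed on are access-restricted.

## The method

All features live on the 68-region Desikan–Killiany (DK) cortical atlas.

**Structural branch.** Each region is summarised by eight morphometric
scalars — surface area *A*, volume *V*, mean and SD of cortical thickness,
and four curvature averages: MCI = (k₁+k₂)/2, Gaussian *K* = k₁·k₂,
ICI = max(K, 0), FI = |k₁|·(|k₁|−|k₂|), with |k₁| ≥ |k₂|. Rather than raw
values, each subject is represented by the antisymmetric **delta tensor**
Δ[i,j,f] = x[i,f] − x[j,f] (68 × 68 × 8): any per-subject offset shared by
all regions (head size, age, scanner gain) cancels in the difference.

**Functional branch.** The 68 × 68 functional-connectivity matrix
F[i,j] = ρ(tᵢ, tⱼ), the Pearson correlation between the mean BOLD time
courses of regions i and j (extractable from a 4-D volume + labelmap).

**Stage 1 — local classification.** Every scalar feature (2 278
connectivity entries; 18 224 delta entries, strict upper triangle) gets a
k-nearest-neighbour classifier (k = 7) under shared stratified 4-fold CV,
yielding per-feature out-of-fold accuracy and per-subject autism
probabilities P_F[i,j] and P_S[i,j,f].

**Stage 2 — ranked-prefix fusion.** Features are sorted by local accuracy;
prefixes of length 1, 2, … are evaluated with a grid-searched random
forest (Gini), the shortest prefix maximising CV accuracy is kept per
modality, and the two optimal prefixes are concatenated and classified for
the fused global diagnosis (accuracy / sensitivity / specificity / AUC,
ASD positive).

**Personalized maps.** V_f(i) = max_{j≠i} P_F(i,j) and
V_s(i) = max_{j≠i,f} P_S(i,j,f): each region's highest autism probability
over all its pairwise features.

**Severity screen.** Every pairwise feature is correlated with the ADOS
total score across scored subjects; features with |r| ≥ 0.32 (p ≈ 0.01 at
n = 61) are flagged, tallied per feature slab, and regions ranked by their
frequency in the significant set.

## Worked example

```python
from neurofuse import GeneratorConfig, generate_cohort_arrays, run_pipeline
from neurofuse.fusion import FAST_GRID

cfg = GeneratorConfig(n_asd=40, n_td=40, t_points=120, n_ados=30,
                      n_missing_fmri=3, seed=1)
cohort = generate_cohort_arrays(cfg)
result = run_pipeline(cohort, seed=1, grid=FAST_GRID, max_prefix=8)
print(result.metrics_summary())
```

prints (run on this machine):

```
{'sMRI': {'chosen_length': 4, 'accuracy': 0.875, 'sensitivity': 0.9,
          'specificity': 0.85, 'auc': 0.95875},
 'fMRI': {'chosen_length': 1, 'accuracy': 1.0, 'sensitivity': 1.0,
          'specificity': 1.0, 'auc': 1.0},
 'fused': {'fused_length': 5, 'accuracy': 1.0, 'sensitivity': 1.0,
           'specificity': 1.0, 'auc': 1.0}}
```

Reading this: the structural branch peaked at a 4-feature prefix with 87.5%
cross-validated accuracy; the connectivity branch separated the classes
with its single best edge (the generator plants strong connectivity
effects); the fused 5-feature classifier is perfect on this small, strongly
planted cohort. `result.maps` holds each subject's V_f/V_s vectors.

The same flow is available from the shell:

```bash
neurofuse simulate --seed 1 --out cohort/
neurofuse fuse --manifest cohort/manifest.csv --smri cohort/smri \
    --fmri cohort/fmri --seed 1 --out run/
neurofuse ados-screen --manifest cohort/manifest.csv --smri cohort/smri \
    --fmri cohort/fmri --threshold-r 0.32 --out screen/
```

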