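# Methods

## The identification problem

Identification treats every subject as a class: with N subjects scanned
T ≥ 2 times, an engine trained on each subject's other scans must assign
a held-out scan to one of all N classes.  The pipeline's currency is a
wide feature table (rows = subject-scans, columns = morphometric
measures); five canonical column sets are defined — the three 148-region
Destrieux modality sets (THICKNESS, AREA, VOLUME), their union with 66
global/subcortical extras (ALL, 510 features), and the 11
large-brain-region composites (11LBR).  The exact composition of the 66
extras is a reconstruction from standard FreeSurfer aseg/global measure
names (the schema docstring flags this); every extra name that appears in
the pipeline's feature-ranking output formats is present, and the counts
are enforced at import (74 regions per hemisphere, 66 extras, 510 total).

## Generative model of the synthetic cohort

    x_ijt = mu_j * (1 + delta_j * (t - 1)) + a_ij + e_ijt,
    a_ij ~ N(0, tau_j^2),   e_ijt ~ N(0, sigma_j^2),  independent.

The subject effect a_ij is constant over time — the anatomical
fingerprint — while aging enters only as a deterministic drift of the
population mean shared by all subjects, so individuality is stable by
construction and the drift cannot aid identification.  Defaults, chosen
once as field-plausible values:

| parameter | default | rationale |
|---|---|---|
| mu_j | thickness U(2, 3) mm; areas log-U(10², 10³) mm²; volumes log-U(10³, 10⁵) mm³ | typical magnitudes of regional FreeSurfer measures |
| tau_j (signature SD) | 0.08·mu_j | gives ICC = τ²/(τ²+σ²) = 16/17 ≈ 0.94, a strong but imperfect test-retest reliability |
| sigma_j (scan noise SD) | 0.02·mu_j | ~2% scan-rescan variability of morphometric pipelines |
| delta_j (annual drift) | −0.005/yr | inside the ≤1%/yr envelope of anatomical change in older adults |
| n_timepoints | 3 | annual scans over two years |

The generator emulates what makes repeated scans identifiable — stable
signatures, small common drift, independent Gaussian measurement error —
and deliberately omits inter-feature correlation structure, heavy tails,
site/scanner effects and subject-specific aging rates.  Passing tests on
this cohort therefore demonstrate correctness of the machinery and the
qualitative behaviour of the engines (perfect identification at high ICC,
chance at ICC = 0, monotone degradation with noise), not the accuracy
figures any particular real cohort would yield.  `variance_components`
inverts the model by one-way random-effects ANOVA per feature after
removing timepoint means (which absorb the drift).

## Engines and numerical choices

**LDA.**  Pooled within-class covariance with divisor n−K; shrinkage
S_λ = (1−λ)S + λ·(tr S/p)·I with default λ = 0.1 — the simplest convex
target guaranteeing positive definiteness, needed because the ALL set
(p = 510) exceeds the within-class degrees of freedom of a 3-scan cohort
(n−K = N).  λ = 0 recovers classic LDA and raises a diagnostic error if
S is singular.  In the zero-within-variance limit (exact repeat scans)
tr(S) = 0 and the identity target falls back to unit scale, so shrunk
LDA degenerates gracefully to nearest-class-mean.  Positive definiteness
is verified by Cholesky at fit time; scores are computed with an LU
solve, which keeps small rational examples bit-exact so that score ties
resolve deterministically (earliest class label).  Priors are uniform:
the protocol gives every subject the same number of training scans.

**WKNN.**  Default k = 3, at most the per-subject scan count, so a
subject's own scans can dominate their neighbourhood.  The neighbourhood
includes every exemplar tied with the k-th smallest distance; votes are
1/d²; a zero distance wins immediately (the ε-regularised 1/(d²+ε)
variant was rejected to preserve exact-match semantics); vote ties break
by the smallest single neighbour distance, then label order.  All
tie-breaks are label-ordered, making predictions invariant to training
row permutation.

**Standardization.**  Features mix mm, mm² and mm³, so Euclidean
distances would be dominated by large volumes; z-scoring (training mean,
sample SD with n−1) is on by default for both engines and is applied
before noise injection.  It provably cannot change full-rank λ = 0 LDA
decisions (affine invariance) and is exposed as `--no-scale`.

## Protocol choices

* **Split**: one test timepoint per subject; default mode draws it per
  subject independently (the most general reading of a random split),
  with a global shared draw and a fixed assignment as alternatives.
* **Noise semantics**: "x% noise" is implemented as additive Gaussian
  noise with SD = level × the training sample SD of each feature,
  applied to test rows only — scale-free, reproducible and monotone in
  level.  Constant training features pass through with a warning.
* **Sweep axes**: noise 0, 0.05, …, 0.40 (nine conditions); cohort sizes
  10, 20, …, 190, clipped to the available cohort, subjects subsampled
  without replacement.  Sweeps accept replicate counts with independent
  seed streams; within a replicate the split is held fixed across noise
  levels so only the degradation varies (this also makes the noise-axis
  Cochran's Q a genuinely matched design).
* **Metrics**: one-vs-rest confusion per subject (TP ∈ {0,1},
  TN = N−1−FP), macro-averaged without weights.  Since true negatives
  dominate, macro ACC and SPEC sit near 1 even when SENS is poor — the
  identity SPEC ≥ 1 − N(1−SENS)/(N−1) is asserted in the tests.
* **Stepwise selection**: greedy forward minimization of Wilks'
  Λ = det(W)/det(T) on the training split, hard cap of 11 features, stop
  when the best candidate improves Λ by ≤ 1e−12.  When a subset's
  dimension exceeds the rank bound n−K, the classifier's shrinkage is
  applied to both scatter matrices; below the bound Λ is computed
  unshrunk so genuine zero-within-variance separation yields Λ = 0
  exactly.  No F-to-enter threshold: the cap is the only stopping bound
  beside the tolerance.
* **Battery**: 2 cross-dataset Cochran's Q (one per engine, zero-noise
  cells) + 10 cross-noise Q (engine × feature set) + 5 exact McNemar
  (engine vs engine per feature set) = 17 tests, Holm-corrected as one
  family.  McNemar defaults to the exact binomial (conservative and
  verifiable by enumeration); the continuity-corrected χ² is available.
  Degenerate inputs are defined, not errors: an all-constant-rows Q and
  a zero-discordance McNemar both return p = 1 with a flag.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated
cohorts: 60 subjects for standard pipeline checks, 100 × 20 seeds for the
chance-level null, 500 for variance-component recovery, 191 for
full-size runs (size-sweep axis and moment checks), 12 for the full
2-engine × 5-set × 9-level battery grid, and 200 simulated batteries of
100 subjects for family-wise error control.  These sizes put every Monte
Carlo assertion at ≥3 standard errors of headroom while keeping a full
run in the order of seconds.

## Known limitations

* The synthetic cohort is diagonal-Gaussian; real morphometric features
  are strongly inter-correlated, so real-data accuracy at a given ICC
  may differ in either direction.
* Cochran's Q relies on its asymptotic χ² null; at very small N with
  extreme proportions the exact permutation null would be preferable.
* The stepwise criterion is plain Wilks' Λ; commercial stepwise-LDA
  implementations add entry/removal F-thresholds and can rank
  differently on correlated candidates.
* No cross-validation beyond the 2-train/1-test design, and no
  probability calibration of identification scores.
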