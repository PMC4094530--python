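# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `panmorph`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Morphometric mapping

A diaphysis mesh is sliced at `n_levels` planes placed at normalized
axial positions (j + ½)/n_levels between the distal and proximal
epiphyseal points (0 = distal), orthogonal to a centroid axis. The axis
starts as the end-to-end line and is refined exactly once by fitting a
line (total least squares) through the per-section centroids; a single
pass keeps the procedure deterministic and is sufficient because the
shaft is nearly straight. Each section outline is obtained from
mesh-edge/plane intersections, ordered by angle about the section
centroid, and resampled by periodic linear interpolation at `n_angles`
equal anatomical angles (anterior 0°, medial 90°, posterior 180°,
lateral 270°). This polar resampling assumes star-shaped cross-sections,
which holds for primate long-bone shafts and for everything the
generator produces; an outline with an angular gap larger than 0.35 rad
(a hole, or multiple intersection curves) raises an error naming the
level. For synthetic meshes the anterior direction comes from the
generator frame; user data must supply one per specimen — no automatic
anatomical orientation is attempted.

The transverse radius of curvature at each outline point is the radius
of the Kasa least-squares circle through a `window` of consecutive
points (periodic wrap). With `window=3` this is exactly the
3-point circumcircle, which the tests use as an independent oracle
(agreement to 1e-9). Near-collinear windows (flat patches) would give
unbounded radii; they are clamped to 10× the section's mean centroid
distance, with a floor of 1e-6, and the number of clamped values is
recorded in the map metadata. Clamping, not erroring, is required
because the median normalization and the PCA need finite values.
Curvature sign is discarded: the map stores the positive radius.

Defaults: 100 levels × 180 angles, window 5 (all config-exposed; the
analysis scripts use 50 × 90, which resolves the 14°-wide ridge while
keeping a full 160-specimen cohort under ~15 s). On an elliptical
cylinder (a=15, b=10) the map reproduces the closed-form radii b²/a and
a²/b at the vertices to better than 2% at the default grid; on a faceted
circular-cylinder mesh the map is constant to the facet chord-sag level
(O(r·Δθ²), ~0.5% at 256 segments) — exact constancy to 1e-6 holds at
the outline level, where no tessellation error exists.

Normalization divides the grid by its median (so median = 1) and is
idempotent; with the length-normalized level coordinate this removes
isometric size, verified by scale-invariance tests at factors 0.5–10.

## Synthetic cohort generator

The generator emulates a 4-taxon × 4-stage cross-sectional study
(10 phenotyped femora per cell, 20 genotyped individuals per taxon,
1000 biallelic loci by default).

Surfaces are tubes r(θ, z) = r0(z) + ridge + modes + noise:

* **Ridge** — a Gaussian bump in θ at 180° (σ = 14°, mid-shaft axial
  window), the linea-aspera analogue, with amplitude
  `ridge_scale × stage_index × heterochrony_rate(taxon)`: developmental
  age drives ridge growth, and per-taxon rate multipliers create
  heterochronic trajectory-length differences.
* **Deformation modes** — a fixed bounded Fourier basis
  cos(mθ − ψ)·cos(kπz), m = 2…5, k = 0…2, ψ ∈ {0, π/2} (24 modes).
  Frequency-1 modes are excluded because they are translation-like and
  nearly invisible to a curvature descriptor. Per-taxon coefficient
  vectors carry the between-taxon signal.
* **Noise** — smooth correlated fields built from the *same* angular
  band with random phases, scaled so the spatial standard deviation is
  `noise_sd`. White vertex jitter is deliberately avoided: curvature
  differentiates the outline, and the curvature gain of an angular
  frequency-m perturbation scales like m² − 1, so noise outside the
  signal band would dominate the descriptor. For the same reason all
  default amplitudes (drift scale 0.1 mm, noise 0.04 mm on a 9–13.5 mm
  radius) keep the curvature response quasi-linear; far larger
  amplitudes saturate at the flat-region clamp and destroy the intended
  ordering of between-taxon distances.
* **Shared growth** (off by default) — a common unit mode direction
  traversed at `heterochrony_rate × shared_growth_scale` per stage,
  parameterized around the mid-ontogenetic shape so that taxa differing
  only in rate have first-to-last chords along the same tangent: the
  morphospace picture of pure rate heterochrony (statistically shared
  directions, different lengths).

Genotypes follow the Balding–Nichols model: per locus an ancestral
frequency p0 ~ U(0.05, 0.95); per taxon k a frequency
p_k ~ Beta(mean p0, variance F_k·p0(1−p0)); individuals Binomial(2, p_k).
The per-taxon drift levels F_k come from the prescribed pairwise
`fst_matrix` by least squares under a star model. Under this generator
the frequency-level Hudson pairwise F_ST equals (F_i + F_j)/2 exactly
(E[within het] = p0q0(2 − F_i − F_j), E[between het] = 2p0q0), so the
decomposition is solved directly on t_ij = (F_i + F_j)/2; the residual
is reported and a non-representable target matrix (negative F_k) raises.
Defaults F_k = (0.08, 0.12, 0.30, 0.60) place the three *troglodytes*
subspecies at subspecies-scale differentiation and *paniscus* at
species scale.

Presets:

* `neutral_congruent` — equal rates, no selection term; each taxon's
  mode coefficients are block means of the *realized* standardized
  allele-frequency displacements (variance F_k under the model), i.e.
  phenotypic divergence is literally proportional to the genotypic
  drift of the same simulation. Congruence is stage-constant.
* `heterochronic_divergence` — rates (1.0, 0.7, 1.35, 1.7), ridge scale
  0.8 mm/age, plus a per-taxon random mode displacement growing
  0.4 mm per stage index (selection-like, independent of drift). At m2
  (stage index 0) divergence is pure drift; toward M3 the non-drift
  terms dominate.

Passing tests on these cohorts show the pipeline recovers the structure
the generator put in; they say nothing about segmentation error, aging
uncertainty, left/right asymmetry, or non-star demographic history in
real data, none of which the generator emulates.

## Estimators and tests

* **Allele frequencies**: alternate count / (2 × non-missing); loci
  missing entirely in a taxon raise with the taxon and locus named;
  pairwise-complete loci are used per taxon pair.
* **Nei standard distance**: −ln(J_AB/√(J_A J_B)) with J's averaged over
  loci; returns +inf when J_AB = 0. The D_A variant (1 − Σ√(p_A p_B))
  is available by flag since published usage of the symbol varies.
* **Chord distance**: per-locus (2/π)√(2(1 − Σ√(p_A p_B))), averaged;
  the variant string is recorded in the matrix metadata because chord
  formulas differ by constants between sources.
* **F_ST**: Hudson ratio-of-averages with the finite-sample correction
  p(1−p)/(n−1) (allele counts), monomorphic-overall loci skipped,
  clipped to [0, 1]; chosen for robustness at small unbalanced samples.
* **D_PPC**: columns centered and scaled by √(p̂(1−p̂)), monomorphic
  columns dropped, missing entries mean-imputed, PCA over individuals,
  Euclidean distance between taxon centroids in the top k = taxa − 1
  PCs.
* **Q_ST**: per PC, two-group ANOVA components — V_W pooled within,
  V_B = (MSB − MSW)/n0 clipped at 0 — aggregated by summed components:
  Q = ΣV_B / (ΣV_B + 2h²ΣV_W), clipped to [0, 1]. Summation preserves
  the variance-ratio interpretation (a mean-of-ratios alternative is a
  config flag). h² default 0.55, PC1–3 by default. Under drift-consistent
  generation (V_B = 2F/(1−F)·h²·V_W) the mean estimate recovers F within
  ±0.05 across F ∈ {0.05, 0.1, 0.2, 0.4} (200 replicates each, in the
  test suite). Because h² enters as a common scale, the *structure* of Q
  is nearly h²-invariant (Mantel r > 0.99 across h² ∈ [0.3, 0.9] on
  homogeneous-variance cohorts), which is what lets the matrix-level
  comparison proceed without a precise heritability estimate.
* **PCO**: classical scaling (double-centering, eigendecomposition);
  axes with non-positive eigenvalues are dropped and zero-padded, the
  negative spectrum is recorded. Deterministic column signs.
* **Procrustes**: both constellations centered and unit-normed, optimal
  rotation (reflections allowed) by SVD, optional scaling; the reported
  distance is the symmetric normalized residual (1 − (Σσ)² with
  scaling), 0 iff similarity-equivalent.
* **Mantel**: Pearson r over upper-triangle entries, one-sided
  (positive association). Two null schemes: simultaneous row/column
  relabeling — enumerated exhaustively for ≤ 6 taxa, so for 4 taxa p has
  resolution 1/24 — and entry permutation (720 orders for 4 taxa),
  which resolves smaller p values. Reports store both; preset-level
  significance statements use the entry scheme, whose resolution
  matches the p values this style of analysis reports.
* **Resampling correlation**: each draw picks a cross-taxon pair, one
  phenotyped specimen of the stage from each taxon (Euclidean score
  distance) and independently one genotyped individual from each
  (allele-sharing distance, 1 − shared-allele proportion); both samples
  are median-normalized; R² is the squared Pearson correlation over
  draws and p comes from permuting the genotype-side distances across
  draws. The independent phenotype/genotype sampling reflects that the
  two specimen sets are disjoint; under label-free data the p values
  are uniform (KS-checked in the suite).
* **Permutation conventions**: mean-shape and trajectory tests permute
  specimens within stage strata; exact enumeration replaces sampling
  whenever the split space has ≤ 10⁴ elements; sampled p values use
  (b + 1)/(n_perm + 1); all seeds are explicit.

## Ancestral reconstruction

Squared-change parsimony minimizes Σ(Δx)²/branch length over internal
nodes — the Brownian-motion ML point estimate — solved exactly via the
graph-Laplacian linear system, per stage and per coordinate
(equivalence with a numerical minimizer is tested on random 4-tip
trees). The default tree is
(((troglodytes, schweinfurthii), verus), paniscus) with unit branch
lengths; real divergence-time ratios can be supplied as Newick. Root
score vectors are mapped back through the PCA
(grand mean + scores·components) into reconstructed LCA curvature maps.

## Pipeline numbers and sizes

The analysis scripts and the acceptance script run the presets at their
default cohort sizes (160 meshes, 96 × 80 mesh grid, 50 × 90 maps,
999/1000 permutations and draws; ~20 s end to end). The replicate-level
tests in the suite use 20–50 seeded replicates at a reduced mesh/map
resolution (64 × 48 / 36 × 60 and below), which resolves every feature
the generator places (ridge σ = 14° ≈ 2.3 map columns at 60 angles) —
chosen so the whole suite stays comfortably repeatable while preserving
each property being tested. All pipeline randomness derives from one
master seed via `stage_seed(c) = (master·1000 + c) mod 2³¹`, and two
identical `run-all` invocations produce byte-identical numeric outputs.

## Known limitations

* The curvature descriptor is only quasi-linear in surface amplitude;
  large features saturate at the flat-region clamp. The map remains a
  valid descriptor there, but distances stop being proportional to
  surface effect sizes — which is also why generator defaults live in
  the quasi-linear regime.
* Polar outline resampling assumes star-shaped sections; pathological
  cross-sections would need arc-length parameterization.
* The star model cannot represent arbitrary pairwise F_ST matrices
  (e.g. strongly non-additive structure); it errors rather than
  silently fitting.
* Genotypes are frequency-level (no linkage, mutation or sequence
  model); R_ST-style statistics and haplotype statistics are out of
  scope.
* With four taxa, matrix-congruence tests rest on six distances; the
  label-permutation Mantel p cannot fall below 1/24, and all stage-wise
  conclusions should be read as structure-level, not entry-level,
  statements.
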