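# Methods

This note documents the models, defaults, and numerical choices behind
`grasprsa`, and what the synthetic-data tests do and do not establish.

## Experimental design model

Nine conditions cross three objects (Wood, BrassUp, BrassDown; the wooden
object weighs 67 g, the two brass-bearing objects 557 g) with three grasps
each. Every condition carries one level of each binary factor:

| factor | levels |
|---|---|
| grasp_axis | cw45 / ccw45 |
| grasp_size | small_2.5cm / large_7.5cm |
| object_mass | light_67g / heavy_557g |

Object mass is fixed by the object (3 light / 6 heavy conditions). A factor
model RDM has entry 1 where two conditions differ on that factor and 0
where they agree; it is symmetric, binary, and zero-diagonal.

**Orthogonal assignment.** The axis and size level assignments are chosen so
all three pairwise model-RDM Pearson correlations (upper triangles, 36
pairs) are exactly zero. `search_orthogonal_assignment` enumerates all
2⁹ × 2⁹ joint assignments with integer-exact covariance arithmetic
(zero is detected without floating-point tolerance); assignments in which a
factor is constant are excluded, since their RDM correlation is undefined.
2,960 exact-zero solutions exist; results are ordered by (max |r|, level
imbalance, bit pattern) and the first is pinned as the default design, so
the default is a pure function of the search criterion.

**A structural trade-off worth knowing.** Exhaustive enumeration shows that
*no* assignment achieves exact-zero model-RDM correlations *and*
mass-balanced level indicators: among all exact-zero solutions the smallest
achievable maximum indicator correlation between factors is 0.5. RDM-level
analyses (all the first-order, second-order, and comfort-RDM correlations)
are unaffected — they operate on the mutually orthogonal RDMs. But
*level-mean contrasts* are not protected: in the default design the size
levels split 4/1 vs 2/2 across heavy/light conditions, so a mass effect on
comfort ratings leaks into the grasp-size t contrast. The level-contrast
t tests should therefore be read as marginal contrasts, not as estimates of
isolated factor effects.

**Trial sequences.** A session has 4 runs × 18 trials (each condition twice
per run). Planning duration is drawn uniformly from {6, 8, 10, 12} s,
execution is 7 s, and the intertrial interval uniform on {10, 11, 12} s
(the source range 10–12 s is discretised to whole seconds), giving
onset-to-onset spacing in [23, 31] s. "Pseudorandom order" is implemented
as seeded greedy first-order counterbalancing: the next condition is drawn
from those still available in the run, preferring the least-used
condition→condition transition, with ties broken at random; plain
within-run shuffling is available as `method="shuffle"`.

## Synthetic data generator

The generator emulates the data at the level the analysis consumes —
normalised beta patterns per (subject, ROI, phase, condition, voxel) — and
plants known representational structure:

- per (ROI, phase), each factor level gets an independent random unit voxel
  vector; a condition's mean pattern is Σ_f w_f · v(f, level_f(c));
- a subject's pattern adds a subject-specific Gaussian perturbation
  (`subject_sd`) and independent Gaussian measurement noise (`voxel_sd`),
  both per voxel.

With a single measurement per condition the two noise sources add in
quadrature and are statistically indistinguishable in any one dataset; they
are kept separate because they are conceptually distinct dials (consistent
between-subject disagreement vs. within-subject measurement error) and both
lower the noise ceiling as intended.

Defaults: 21 subjects, 9 ROIs, 2 phases, 65 voxels (a 15-mm-diameter
spherical ROI at 3-mm isotropic resolution is ≈ 1767/27 ≈ 65 voxels),
planted weight 1.0, `subject_sd = voxel_sd = 0.3`. The noise level was set
once so that the planted-factor model correlation averages ≈ 0.3 with noise
ceilings ≈ (0.27, 0.38) — the scale typical of ROI-level RSA with ~20
subjects. The default planted-weight map places axis in early-visual,
dorsal, and motor regions during planning, size in ventral and premotor
regions in both phases, and mass in ventral/sensorimotor regions during
execution only, mirroring the qualitative pattern reported for this
paradigm.

Comfort ratings are baseline 8 minus per-factor penalties (mass 2.5, axis
0.6, size 0) plus N(0, 1) noise, clipped to [1, 10]; real-valued by default
(`rating_integer=True` rounds). Mass dominates comfort by design.

**What the generator does not emulate:** BOLD time courses, HRF convolution
and GLM estimation, spatial voxel correlations, run structure and trial
averaging, head motion, or non-Gaussian beta distributions. Passing
recovery/calibration tests therefore show that the *analysis chain* is
correct and calibrated for patterns with this covariance structure — not
that the pipeline's significance maps would replicate on real data.

## First-order analysis

Dissimilarity is correlation distance 1 − r, so RDM entries lie in [0, 2];
a zero-variance condition pattern raises an error naming the condition.
Per-voxel z-scoring across conditions is available but off by default
(inputs are treated as already-normalised betas). RDM-to-RDM comparisons
default to Pearson; Spearman is a config option.

Group summaries average raw correlations (not Fisher-z); Wilcoxon
signed-rank p-values are exact (full sign-pattern null distribution) when
n ≤ 25 with untied absolute values and no zeros, otherwise a normal
approximation with tie and continuity corrections; zeros are discarded by
default (`pratt` optional). FDR uses Benjamini–Hochberg. The correction
family is configurable: `per_model_phase` (default — 9 ROIs per model ×
phase, matching per-panel presentation), `per_phase` (27 tests), or
`global` (54). Noise ceilings use the same correlation method as the
model–data comparisons. With a single subject, results are produced with
the ceiling marked unavailable.

## Second-order analysis

Group-average RDMs are correlated between ROIs within each phase (the
matrix is symmetrised; m = R(R−1)/2 Bonferroni tests) and across phases
(full R × R including self-pairs; m = R²). Two p-value modes:

- **parametric** (default): t = r √((n−2)/(1−r²)) with n = 36 pair entries,
  df = 34. RDM entries sharing a condition are not independent, so this is
  approximate and somewhat anticonservative;
- **permutation**: condition labels of one RDM are permuted jointly over
  rows and columns (10,000 seeded permutations by default), which respects
  the RDM dependence structure and is the safer choice for publication-grade
  inference.

Clustering uses average linkage on 1 − r (single/complete optional); ROIs
are sorted by label before linkage so the tree is independent of input
order. The embedding is classical (Torgerson) MDS: double-centre the
squared distance matrix, take the top-2 eigenvectors, clip negative
eigenvalues to zero; coordinates are centred and each axis is sign-fixed by
its largest-magnitude coordinate, making the output deterministic up to the
rigid ambiguity inherent to MDS.

## Comfort analysis

Comfort RDMs are absolute rating differences |rᵢ − rⱼ| (an RDM must be a
symmetric non-negative dissimilarity, which rules out signed differences).
Factor contrasts are two-tailed paired t tests on per-subject level means
(df = n − 1); zero-variance differences raise. Comfort↔model significance
mirrors the neural analysis (per-subject correlations + one-tailed
Wilcoxon), with the group-average-RDM correlation reported descriptively;
when a model is exactly orthogonal to every subject's comfort RDM the test
is reported as p = 1 rather than erroring. Comfort↔neural analysis
correlates each subject's neural RDM with the *group-average* comfort RDM,
then applies Wilcoxon + FDR per phase.

## Numerical and interface choices

- Upper-triangle vectorisation order is row-major (1,2), (1,3), …, (n−1,n),
  pinned and tested; averaging commutes with vectorisation.
- RDM symmetry/diagonal tolerance is 1e-12; matrices are symmetrised on
  construction.
- Constant RDM vectors raise explicit errors everywhere a correlation is
  taken — NaN is never returned.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration + seed yields
  byte-identical output tables (the configuration hash embedded in each
  table excludes the output path).
- Interchange formats are plain CSV/JSON/YAML; the pattern reader validates
  a complete (subject, roi, phase, condition) crossing and names the first
  missing cell or duplicated row.

## Verification problem sizes

The acceptance checks run at the study's native scale where that is cheap
(21 subjects × 65 voxels for recovery and calibration; all 262,144
assignments for the design search) and at reduced scale where iteration
count dominates (noise-ceiling sweep: 200 six-subject datasets; null
calibration: 500–1,000 single-ROI analyses; cross-phase null: 100
four-ROI replicates). Sizes are stated alongside each reported value.

## Known limitations

- The pinned design is one of 2,960 exact-zero solutions and may differ
  from any particular published assignment by relabeling; all are
  equivalent for RDM-level analyses.
- The parametric second-order p-values treat the 36 RDM entries as
  independent; use the permutation mode when that matters.
- The generator's noise is white across voxels; spatially correlated noise
  would lower effective pattern dimensionality and shift absolute
  correlation scales.
- Ratings are generated (and analysed) as continuous; ordinal treatment of
  the 1–10 scale is out of scope.
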