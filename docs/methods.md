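# Methods

This note documents the models and procedures `tractokit` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic generators do and do not emulate.

## Tract profiles

A tract is a named group of streamlines in RAS+ mm.  Profile extraction
runs, per tract:

1. **Resampling.**  Every streamline is resampled to `n_nodes` (default
   100) points equally spaced in cumulative arc length, by linear
   interpolation of each coordinate against the cumulative chord length.
   Endpoints are preserved exactly; consecutive duplicate points are merged
   first; zero-length streamlines raise.

2. **Orientation harmonization.**  Node *j* must mean the same anatomical
   position in every streamline, so each streamline is kept or reversed,
   whichever minimizes the summed node-to-node distance to a reference
   streamline (the first streamline that is not a length outlier;
   configurable).  The comparison is strict, making the operation
   idempotent.

3. **Outlier cleaning.**  Up to `n_rounds` = 5 rounds: at each node the
   survivors' mean and 3×3 covariance are estimated; a streamline's score is
   its per-node Mahalanobis distance averaged over nodes, and it is removed
   when the score exceeds `distance_threshold` = 3 (Mahalanobis distance is
   already in SD units).  Afterwards, survivors whose arc length deviates
   from the survivor mean by more than `length_threshold` = 5 sample SDs are
   removed.  A round that removes nothing stops the iteration.  Covariances
   whose smallest eigenvalue is below 1e-8 receive a ridge of
   (1e-6·trace/3 + 1e-12)·I, so degenerate bundles (e.g. identical
   streamlines) are handled without exceptions and without removals.
   Groups with fewer than 10 streamlines are not cleaned (a warning is
   logged): the covariance estimates would be meaningless.  The Mahalanobis
   criterion is orientation sensitive, so cleaning assumes step 2 has run
   (the pipeline guarantees it; `clean_group` used standalone documents it).

4. **Weights.**  At node *j* the weight of streamline *s* is
   1/(d<sub>sj</sub> + ε) normalized to sum to 1 over streamlines, where
   d<sub>sj</sub> is the Euclidean distance to the coordinate-wise median
   across streamlines and ε = 1e-10 mm guards the exact-median case.  This
   literal inverse-distance form is the default; the classic
   Gaussian-of-Mahalanobis weighting is available via
   `weighting="gaussian"`.  Note the inverse-distance form is unbounded: a
   streamline passing very near the per-node median can dominate the
   profile, which makes profiles sensitive to tiny coordinate perturbations
   in that configuration (see Limitations).

5. **Sampling.**  Scalar maps are sampled by trilinear interpolation at the
   node positions (voxel indices are 0-based, the affine maps voxel
   centers).  Samples falling outside the volume — including the edge
   half-voxel, where interpolation would blend with padding — are excluded
   and the remaining weights renormalized; a node with no in-volume samples
   is NaN, and an entirely non-overlapping tract yields a flagged-missing
   profile with a logged warning.

Invariants tested: constant maps give constant profiles under any cleaning,
weighting and orientation; per-node weights sum to 1 within 1e-12; profiles
are invariant to streamline order and equivariant under rigid translation of
tractogram and map together.

## TRK and TRX formats

**TRK** (TrackVis v2) has a fixed 1000-byte header and float32 coordinates
in "voxel-mm" space: 0-based voxel indices with a corner-of-voxel origin
times voxel size, i.e. `voxmm = (vox + 0.5) * voxel_size`.  The conversion
from internal RAS mm is explicit and is the format's classic
interoperability trap; round trips are verified against nibabel's TrackVis
reader as an independent oracle.  Round trips are bit-exact whenever the
affine-induced map preserves float32 representability (e.g. diagonal
power-of-two voxel sizes with translation = voxel_size/2, as used in the
round-trip tests); general affines round-trip to float32 precision.  One
file stores one streamline group, so a segmented subject needs one file per
tract.  Read errors (bad magic, truncated records, header/record count
disagreement) raise explicit format errors naming the inconsistency.

**TRX** here is a zip container with `header.json` (dimensions, voxel
sizes, voxel-to-RAS affine, vertex/streamline counts), a flat
`positions.3.<dtype>` array (float16/32/64, RAS mm), `offsets.uint64`
(start index per streamline; the last offset plus the last streamline's
length must equal the vertex count), and one `groups/<name>.uint32` index
array per tract — a whole multi-tract subject in one file.  Unknown entries
are ignored on read (forward compatibility); per-vertex/per-streamline data
arrays are out of scope.  DEFLATE compression is optional (level 6 by
default, configurable).  Half-float storage bounds the coordinate rounding
error at 2<sup>-11</sup> relative.

The fidelity harness writes a subject both ways, re-extracts all profiles
from each file with identical settings, and reports the maximum relative
profile difference, the TRX/TRK byte ratio, and elapsed-time / peak-memory
ratios.  The time and memory ratios are hardware dependent and are reported
for information only — no test asserts them.

## Heritability

For twin pair *i*, node *j*, tract *k*, Haseman–Elston regression fits

(Y<sub>ijk1</sub> − Y<sub>ijk2</sub>)² = α + β·π<sub>i</sub>,
π<sub>i</sub> = 1.0 (MZ) or 0.5 (DZ),

by ordinary least squares independently per (tract, node), dropping pairs
with missing values node-wise; both π levels must be present with at least
two pairs each, otherwise the slope is unidentifiable and the fit raises.
Heritability is h²<sub>jk</sub> = −β/(2σ²<sub>jk</sub>).

Two conventions for σ²<sub>jk</sub> are implemented and never silently
substituted:

* `squared_difference`: the variance across pairs of the squared difference
  itself — the convention as printed in the field's along-tract reports;
* `trait`: the variance of the trait across all cohort members.  Under the
  additive-genetic generative model E[(Y₁−Y₂)²|π] = 2σ²(1 − π·h²), so
  E[β] = −2·Var(trait)·h² and only this convention yields an asymptotically
  unbiased ĥ².  It is therefore the default in parameter-recovery
  experiments, while `squared_difference` remains the config default.

Estimates are reported raw — not clipped to [0, 1] — unless `clip=True`;
zero-variance nodes are flagged NaN.  Confidence intervals use a percentile
bootstrap (default 1000 replicates) resampling pairs with replacement
within zygosity strata, so both π levels survive every replicate.  The CI
method is this package's choice; nothing in the estimator prescribes one.

**Recovery experiment.**  `recovery_experiment` simulates cohorts on a grid
of true h² values, re-estimates, and reports per-replicate errors.  Each
replicate's estimate is the mean of the node-wise estimates over a 100-node
profile (the pipeline's profile length; nodes are independent draws).  A
single-node HE estimate at 500+500 pairs has a sampling SD of roughly
0.10–0.18 depending on h², so the along-profile mean is the quantity with
a usefully small error (≈0.01–0.02 mean absolute error at this size).

## Prediction

Profiles are flattened tract-major (tract, then metric, then node): 24
tracts × 4 metrics × 100 nodes = 9,600 features in 96 groups of 100, one
group per (tract, metric) pair (`group_by="tract"` collapses to per-tract
groups).  Missing values are mean-imputed with a logged count; subjects
with no finite features are excluded with a warning.  Precomputed external
feature tables (e.g. local-connectome matrices) are accepted as a single
trivial group.

Model objectives, for n training samples and groups g of size p_g:

* LASSO: 1/(2n)‖y − Xw‖² + λ‖w‖₁ (scikit-learn coordinate descent);
* Sparse Group LASSO: 1/(2n)‖y − Xw‖² + λ[(1−a)Σ_g √p_g‖w_g‖₂ + a‖w‖₁],
  solved in-package by FISTA with the exact proximal operator (elementwise
  soft-threshold, then groupwise shrinkage), warm-started along the λ path.
  With a = 1 the objective reduces exactly to the LASSO; the solver is
  cross-checked against scikit-learn to 1e-6 on that reduction.  The mixing
  parameter defaults to a = 0.95.

**Cross-validation.**  Outer loop: k = 5 folds assigned at the family
level — families are shuffled (seeded), stably sorted largest-first, and
greedily assigned to the smallest fold, so subjects of one family never
straddle folds and fold sizes stay balanced.  Per outer fold, features are
standardized on the training subjects only (zero-variance features get unit
scale), the response is centered, and an inner family-grouped 5-fold CV
selects λ from 100 log-spaced values spanning 4 decades below the
data-driven λ_max by validation error; the model is refit on the outer
training set at the selected λ.  Pooled out-of-sample predictions give the
headline R²; per-fold values are also reported.  Only λ is tuned — the SGL
mixing parameter is fixed per run.

**Repeated CV.**  `repeat_cv` reruns the nested CV with distinct fold seeds
(default 100 repeats).  Each repeat's weight vector is the mean of its
outer-fold coefficient vectors on the original feature scale; across
repeats the per-feature mean, 95% percentile interval, and variance are
reported, and the scalar weight-stability summary is the across-repeat
variance averaged over features — the quantity on which grouped and plain
L1 penalties are compared.  (The aggregation into a single scalar is this
package's definition; other summaries are possible.)

## Synthetic data

The generators emulate the statistical structure the analysis consumes, not
diffusion physics: no raw diffusion-weighted signal, gradient tables, or
scanner artifacts.

* **Bundles.**  Streamlines are a centerline (arc-length resampled) plus a
  smooth perpendicular offset of constant magnitude radial_sd·√2 whose
  direction winds along the tract: a cubic spline through 13 phase-angle
  knots whose increments have fixed magnitude π/4 and random signs.
  Interpolating the phase (rather than the offset components) means no
  streamline ever crosses the bundle core, and fixing the per-knot
  increment magnitude gives every streamline the same winding energy, so
  the genuine ensemble is exchangeable: lengths and Mahalanobis scores
  concentrate tightly and planted outliers (displaced by `outlier_offset`
  \> 3·radial_sd perpendicular to the tract, indices recorded in metadata)
  separate cleanly at the 3 SD threshold.  At every spline knot the offset
  magnitude is exactly radial_sd·√2, so each perpendicular component has
  second moment radial_sd² and the RMS perpendicular distance at a knot is
  √2·radial_sd — the closed form the generator tests check.  Half of the
  streamlines are stored reversed to exercise orientation harmonization.
  What this does **not** emulate: real bundles fill their cross-section
  with a density peak at the core and have genuinely heterogeneous
  streamline shapes; passing the cleaning tests here shows the procedure
  separates a coherent ensemble from planted geometric outliers, not that
  it makes optimal keep/drop decisions on real anatomy, where some genuine
  streamlines do sit near the 3 SD boundary.

* **Subjects.**  `make_subject` arranges 24 bundles (standard tract names)
  in a head-centered 2 mm grid (coordinates ≈ ±80–96 mm, as in
  ACPC-aligned data) with smooth analytic FA/MD/MK/AWF fields obeying the
  metric range invariants (FA, AWF ∈ [0,1]; MD > 0), plus optional voxel
  noise.  Tissue-property values follow these invariants rather than any
  empirical histogram.  Default 500 streamlines per bundle at 100 points.

* **Twin cohorts.**  Traits are simulated directly at node level:
  Y = μ + g + e with Var(g) = h²σ², Var(e) = (1−h²)σ², corr(g₁,g₂) = π
  via a shared/individual decomposition, independent environments, and the
  drawn genetic components retained in metadata for diagnostics.  The
  default simulated cohort size (138 MZ + 75 DZ pairs) mirrors a large
  twin study's analyzable complement.

* **Phenotypes.**  A linear combination of standardized profile features
  restricted to chosen (tract, metric) groups plus Gaussian noise; subjects
  partition into families (default: size-2 sibling pairs for half the
  cohort, singletons for the rest).  The generating signal and weights are
  returned so tests can compute oracle R².

All draws flow through explicit integer seeds (`numpy.random.default_rng`);
no global random state.  Identical seeds give bit-identical outputs on one
platform.  Randomness is Gaussian except where stated above (winding phases
and signs, outlier directions, orientation reversals are uniform/sign
draws).

## Problem sizes in tests

The shipped tests run the estimators at sizes chosen to make their
statistical claims decisive yet quick: heritability recovery at 500+500
pairs × 100 nodes × 100 replicates; the format harness at the full 24 × 500
subject; prediction checks at 50–200 subjects with 40–160 features and λ
grids of 5–30 values (the 100-value default grid is exercised through the
CLI path).  These are the package's test conditions, not statements about
the method's limits.

## Known limitations

* The literal inverse-distance weight is unbounded near the bundle median;
  with ε = 1e-10 a streamline within microns of the per-node median takes
  effectively all the weight.  The Gaussian weighting switch avoids this at
  the cost of departing from the inverse-distance definition.
* The squared-difference variance convention does not give an unbiased h²
  under the additive model; it is provided because it is the printed
  convention in along-tract heritability reports, and the discrepancy is
  surfaced rather than resolved.
* HE regression here handles twin pairs only — no SEM/ACE variance
  components, kinship matrices, or non-twin siblings in estimation
  (families matter only for fold construction in prediction).
* The TRX dialect covers positions, offsets and groups; streamline/vertex
  metadata arrays are read-ignored and not written.
* TRK bit-exactness depends on the affine, as described above.
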