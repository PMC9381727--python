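# Methods

This note documents the models, parameters and numerical choices behind
`vitrevol`, and what the synthetic-phantom experiments do and do not show.

## Coordinate and plane conventions

Volumes are `(x, y, z)` grids: `x` the 12 mm en-face horizontal axis, `y`
the 9 mm vertical axis, `z` the 2.6 mm depth axis with the retina at high
`z`. Physical positions are voxel centers, `(i + 0.5)·spacing`. Planes:
*axial* frames are `(x, z)` images stacked along `y`, *sagittal* frames
`(y, z)` stacked along `x`, *coronal* (en-face) frames `(x, y)` stacked
along `z`. The default acquisition grid is 256 × 192 × 56 voxels
(0.046875 × 0.046875 × ~0.0464 mm), deliberately anisotropic so the
isotropic-rescaling stage is exercised.

## Phantom model

The phantom emulates a posterior-segment SS-OCT scan:

* **Retina:** a uniform bright band for `z ≥ retina_surface_z`
  (default 2.1 mm).
* **Gel and fluid:** vitreous gel at reflectivity 0.45, fluid cavities at
  0.08, retina at 0.85 (arbitrary units in [0, 1]; order
  fluid < gel < retina is enforced).
* **Cavity shapes:** PMP as a half-ellipsoid (default semi-axes
  3 × 2.5 × 0.8 mm, flattened in depth) resting base-down on the retinal
  surface over the fovea; CC as a truncated cone (base radius 0.9 mm, apex
  0.4 mm, length 1.2 mm) standing on the retina in front of the disc;
  optional ellipsoidal accessory cavities; optional straight cylindrical
  PMP–CC canal. Every primitive has a closed-form volume (half-ellipsoid
  2πabc/3, truncated cone πL(R² + Rr + r²)/3) and a quadrature surface area
  (midpoint rule on the parametric surface, flat caps added analytically),
  used as oracles that never touch the pipeline's marching-cubes path.
* **Speckle:** multiplicative gamma noise with mean 1 and shape `k`
  (default 4, i.e. ~50% intensity SD — fully developed speckle;
  `speckle_shape=None` disables noise for two-intensity fixtures). Speckle
  never alters the ground-truth masks. Cavity walls are not hyperreflective
  by default; an optional boundary line is available since real gel–fluid
  interfaces can appear bright.
* **Raters:** a simulated annotator labels frames `0, s, 2s, …` with stride
  `s ∈ {8, 9, 10}`. Each labeled frame is the true cross-section perturbed
  by one morphological dilation (positive draw) or erosion (negative draw)
  of disk radius `|N(0, σ)|` rounded to pixels, plus random omission of
  small cross-sections. This is the simplest boundary-uncertainty model
  that supports inter-examiner reliability experiments; it does not model
  anatomically correlated errors, fatigue, or systematic over/under-calling
  by an individual examiner.

What the phantom does **not** emulate: interferometric image formation, eye
motion and blink artifacts, depth-dependent signal roll-off, the vitreoretinal
interface texture, or partial-volume gray levels at cavity walls (the
rasterization is binary at voxel centers). Passing recovery tests on
phantoms therefore demonstrates correctness of the pipeline's geometry and
statistics, not clinical segmentation accuracy on patient scans.

## Segmentation

**Trained pathway.** One model per plane per eye. The network is a residual
encoder–decoder on 3-frame stacks: stem convolution, residual block,
average-pool ×2, residual block, average-pool ×2, residual bottleneck, then
two nearest-neighbor upsamplings with additive skip connections and residual
blocks, and a 1×1 output head — constant filter depth (default 32) and
pixelwise binary cross-entropy on logits, optimized with Adam at learning
rate 2 × 10⁻⁴ (defaults chosen for slow, smooth convergence). It is
implemented directly on numpy (im2col convolutions, hand-written backward
passes), is fully seeded, and at the package's reduced CPU scale (filter
depth 8–16, ≤128-pixel frames) trains in seconds to minutes. Every fifth
labeled frame is held out for validation when ≥5 labels exist; the returned
parameters are the best-so-far checkpoint under the monitored loss, so
longer training can never return a worse model. Prediction binarizes the
sigmoid output at 0.5, and labeled frames are re-predicted rather than
copied, making the output a pure function of the trained model (the
alternative — overwriting predictions with manual labels — is equally
defensible; re-prediction was chosen because it simplifies the reliability
analysis).

**Fallback pathway.** A deterministic baseline with the same contract:
scan 256 intensity quantiles of the labeled frames for the threshold
maximizing Dice against the labels (fluid is hyporeflective, mask =
intensity < t), apply it to every frame, and keep per frame only connected
regions overlapping the depth band spanned by the labels (± 8 voxels).
Identical inputs give identical masks.

A per-voxel threshold has a known bias under heavy speckle: at the
Dice-optimal threshold the interior detection probability p drops below 1,
and the subsequent window-majority (median) filter places the recovered
boundary where the local foreground fraction crosses 0.5, i.e. shifted
inward by roughly `(f* − 0.5)·w` window widths, with `f*` the fluid fraction
satisfying `p·f* + q·(1−f*) = 0.5`. At speckle shape 4 this costs ~15–20% of
cavity volume; at shape ≥16 it is negligible. The CNN, which uses spatial
context, does not share this bias; geometry-recovery checks therefore use
mild speckle for the fallback and moderate speckle for the CNN.

**Fusion.** Voxelwise 2-of-3 majority with the per-voxel vote count
retained. With three voters no ties are possible; fusion is symmetric,
idempotent on agreement, and bounded between intersection and union of the
plane masks (property-tested).

## Postprocessing

The 9 × 9 × 9 median filter on a binary mask equals the window majority, and
is computed as an exact integer box count via separable cumulative sums —
bit-identical to a brute-force window median but fast at full scan size.
Boundaries use edge-including reflection ("symmetric" padding), so cavities
touching the scan border are not spuriously eroded. Two measured properties
worth knowing:

* Majority filtering is **not** idempotent on convex solids: it behaves
  like a discrete curvature flow, rounding convex corners a little more on
  every pass (a 21³ cube loses ~14% of its voxels to the first 9³ pass and
  keeps shrinking). The pipeline applies it once.
* The filter's physical window scales with voxel size. At the default
  0.047 mm voxels the 9³ window spans 0.42 mm and erodes the PMP rim
  (meridional curvature radius c²/a ≈ 0.21 mm) by several percent of
  volume; scaled-down grids use proportionally smaller windows (5³ or 3³)
  for the same reason.

An optional small-component cull (26-connectivity, off by default) removes
speckle islands.

## Biometry

* **Rescaling:** nearest-neighbor resampling onto an isotropic lattice with
  edge 12/256 mm = 0.046875 mm, whose cube is 1.0300 × 10⁻⁴ mm³ — the
  printed per-voxel calibration. (The cube volume is the published
  constant; 12 mm/256 A-scans is the natural en-face division that
  reproduces it.) Volume is preserved to within boundary quantization
  (<2% at cavity scale).
* **Components:** connected components under 6-connectivity (conservative:
  an anatomical "connection" must be a face-shared fluid path), labeled in
  descending size with lexicographic tie-break.
* **Classification:** the component whose en-face projection covers the
  foveal column is the PMP; the disc column gives the CC; any others are
  "other". If one component covers both landmarks it is split by two-source
  geodesic distance (uniform-cost 6-connected shortest path from the two
  landmark columns; ties to PMP) and flagged connected. Some attribution
  rule is required because separate PMP and CC measurements must exist even
  when the cavities communicate; geodesic splitting is deterministic and
  testable, but voxels of a shared canal are necessarily assigned to one
  side or the other.
* **Volume:** voxel count × voxel cube.
* **Surface area:** marching cubes on the (zero-padded) binary indicator at
  iso-level 0.5, triangle areas summed, scaled by the voxel edge. No
  pre-smoothing, matching a strictly voxel-based measurement. **Calibrated
  bias:** on digitized spheres (r = 10, 20, 40 voxels) the measured area
  exceeds 4πr² by +9.2/+8.5/+8.7%, and phase-averaging over sub-voxel
  center offsets gives +8.4/+8.7/+8.8% — a persistent ~+9% overestimation
  that converges to a constant, not to zero, because binary input pins all
  isosurface vertices to edge midpoints. Surface-area recovery tolerances
  (±10%) are calibrated from these runs. A single voxel yields the analytic
  octahedron, area √3·e².
* **Propagated error:** ΔV = A·e/2 spreads half a voxel of boundary
  uncertainty over the measured surface (for a digitized sphere this equals
  the half-voxel shell volume up to the marching-cubes bias, i.e.
  ΔV/V ≈ 3e/2r); ΔA = (A₊ − A₋)/2 from one-voxel dilation/erosion, with
  A₋ = 0 and a warning flag if erosion empties the structure. The exact
  formula behind the published ± values is not documented anywhere we know
  of; this rule is a transparent, tested convention of this package and
  matches published examples only to within a factor ~2.
* **Connection detection:** PMP and CC communicate iff their voxel sets
  share one 6-connected component of the pre-split grid.

## Statistics

Raw-score Cronbach's alpha for k = 2 raters,
α = 2·(1 − (σ²_A + σ²_B)/σ²_{A+B}), with sample (n−1) variances; undefined
(explicit error) at zero total variance. Pearson r with two-sided
t-distributed p (df = n−2). Group comparisons run Shapiro–Wilk on each
group first; the pooled-variance Student's t is always reported, and if
either group rejects normality at 0.05 the result is flagged and a Wilcoxon
rank-sum test is reported alongside (the fallback is this package's choice;
the alternative of silently t-testing was rejected as fail-quiet). No
multiple-testing correction is applied, mirroring the original analysis —
a documented limitation. Cohort tables report mean ± SD and range; a
single-record cohort reports SD = 0 by convention.

**Reliability experiment.** For n eyes (default 6), phantoms with ~15%
eye-to-eye geometric variation are each labeled independently by two
simulated examiners and pushed through the full pipeline; Cronbach's alpha
is computed over the paired whole-cavity volumes and areas. Zero-error
raters give α = 1.000 exactly. With independent jitter (SD 2 px) alphas
drop below 1, but only slightly, and area reliability exceeds volume
reliability — the reverse of the published patient-data ordering — because
in the fallback pathway rater labels influence the output only through the
scalar threshold and the depth band. Reproducing the published alphas
(0.92/0.82) would require patient scans and examiner behavior that no
phantom provides; the experiment here validates the *machinery*
(experimental design, alpha computation, end-to-end determinism), not the
published coefficients.

## Problem sizes and defaults used in verification

Geometry recovery runs the fallback pipeline on a 384 × 288 × 84 phantom
(mild speckle, shape 30), where raster quantization and median-filter rim
erosion are both below the 5% volume tolerance; the learned-segmenter check
uses a 128 × 96 × 48 phantom with moderate speckle (shape 8), filter depth
16, 60 epochs, batch 4, and a 3³ median window appropriate to the coarse
grid; reliability and connection suites use 128 × 96 × 48 phantoms with a
5³ window. These sizes are the package's chosen verification conditions;
all are seeded and rerun from scratch by `scripts/acceptance.py`.

## Known limitations

* No patient data: all quantitative claims are about analytic phantoms.
* The fallback segmenter's speckle-dependent boundary bias (above).
* Binary marching cubes overestimates curved-surface area by ~9%; reported
  areas are not bias-corrected, matching the voxel-based measurement
  convention.
* The CNN is CPU-scale; full-resolution training at filter depth 32 on
  256-pixel frames is possible but slow (minutes per epoch).
* The error-propagation rule is a convention, not a derived estimator.
* Canal voxels of a connected PMP–CC pair are attributed by geodesic
  proximity; other attribution rules would shift a few percent of volume
  between the structures.
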