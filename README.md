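# vitrevol

**3D modeling and volumetry of posterior vitreous fluidic cavities from OCT
volume scans.**

The posterior vitreous of the eye contains fluid-filled cavities — the
premacular vitreous pocket (PMP), a flattened bowl of liquefied vitreous in
front of the macula, and Cloquet's canal (CC), a funnel-shaped channel in
front of the optic disc — whose size and connectivity change with age and
disease. `vitrevol` reimplements, as a tested and reusable pipeline, a
machine-learning approach for turning swept-source OCT volume scans
(12 × 9 × 2.6 mm posterior-segment field) into quantitative 3D cavity
models:

1. **Sparse labeling.** The hyporeflective fluid is annotated on roughly
   every 8–10th frame of each of the three orthogonal planes (axial,
   sagittal, coronal).
2. **Per-plane segmentation.** For each plane, a residual encoder–decoder
   CNN (constant filter depth 32, learning rate 2 × 10⁻⁴) is trained on the
   labeled frames; the input for each frame is a 3-channel stack of the
   frame before, the frame itself and the frame after. The trained model
   then annotates every frame of that plane. A deterministic
   intensity-threshold fallback segmenter with the same interface supports
   fast, exactly reproducible runs.
3. **Majority fusion.** A voxel is fluid iff at least 2 of the 3 plane
   segmentations mark it.
4. **Postprocessing.** A 9 × 9 × 9 median filter denoises the fused binary
   model.
5. **Biometry.** The mask is resampled to an isotropic lattice whose voxel
   cubes to 1.03 × 10⁻⁴ mm³ (edge 12/256 mm); volume is voxel counting,
   surface area comes from marching cubes on the binary indicator, each with
   a propagated segmentation error (ΔV = A·e/2; ΔA from one-voxel
   dilation/erosion). Components are attributed to PMP/CC via the fovea and
   disc landmarks — a merged component is split by two-source geodesic
   distance and flagged as a PMP–CC connection.
6. **Statistics.** Cronbach's alpha for two-rater reliability, Pearson
   correlation, Shapiro–Wilk-gated Student's t tests, and cohort summary
   tables.

Because no patient scans ship with the package, a **synthetic phantom
generator** produces OCT-like volumes (bright retinal band, gamma-speckled
gel, dark cavities with analytic shapes: half-ellipsoid PMP, truncated-cone
CC, optional accessory cavities and a PMP–CC canal) together with exact
ground-truth masks, closed-form volumes, and quadrature surface areas, plus
simulated human raters with controllable boundary jitter. Every pipeline
stage is verified against these analytic oracles.

## Worked example

```python
from vitrevol import (PhantomSpec, RaterErrorModel, PipelineConfig,
                      run_phantom_eye, analytic_surface_area)

spec = PhantomSpec(grid_shape=(384, 288, 84), seed=1,
                   speckle_shape=30.0).with_default_cavities(None)
metrics, model = run_phantom_eye(spec, RaterErrorModel(frame_step=9, seed=4),
                                 PipelineConfig())
pmp = metrics.get("PMP")
print(pmp.volume_mm3, spec.pmp_geometry.volume())
print(pmp.area_mm2, analytic_surface_area(spec, "PMP"))
```

On this mild-speckle phantom the full fallback pipeline reports (one run,
seeded):

```
PMP volume  12.55 mm³   (analytic 12.57 mm³,  −0.1%)
PMP area    51.42 mm²   (quadrature 51.17 mm², +0.5%)
CC  volume   1.61 mm³   (analytic  1.67 mm³,  −3.9%)
CC  area     8.09 mm²   (quadrature 8.36 mm², −3.2%)
PMP–CC connected: False
```

i.e. both cavities are recovered within a few percent of their closed-form
sizes, and the disjoint phantom is correctly reported as unconnected.

The CLI exposes every stage (`simulate`, `annotate`, `train`, `segment`,
`fuse`, `postprocess`, `quantify`, `export-mesh`, `reliability`,
`cohort-stats`, `run`). A self-contained demo:

```bash
vitrevol run --demo --seed 7 --outdir demo_run
```

```
whole: V = 11.04 ± 1.25 mm³, A = 53.52 ± 3.49 mm²
PMP: V = 9.68 ± 1.06 mm³, A = 45.21 ± 2.51 mm² (analytic V = 12.57 mm³)
CC: V = 1.36 ± 0.23 mm³, A = 9.74 ± 1.74 mm² (analytic V = 1.67 mm³)
PMP-CC connected: True
```

The demo runs the threshold fallback on a coarse, heavily speckled phantom,
where a per-voxel classifier systematically under-segments the boundary —
the ± values are the propagated segmentation errors, and the bias is
discussed in `docs/methods.md`; the trained CNN pathway and finer grids
recover the geometry much more closely.

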