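# octmosaic

Quantitative *in vivo* imaging of the adult zebrafish cone photoreceptor
mosaic from optical coherence tomography (OCT) volume scans.

Zebrafish are a workhorse model for retinal development and disease, and
their cone-rich retina tiles into a crystalline mosaic of spectral subtypes.
Assessing that mosaic non-invasively from OCT runs into two obstacles:

1. **The retina is curved.** A flat depth slab through the volume mixes
   retinal layers across the field, so the native en face projection shows
   the cone mosaic only where the slab happens to cross the photoreceptor
   band.  `octmosaic` builds *contour-guided summed volume projections*
   (SVPs): a per-B-scan contour with 3–15 control points tracks the sublamina
   of interest, and intensity is summed over a 10–20 px window centred on the
   interpolated contour depth.  Placing the contour on the most anterior
   photoreceptor band isolates the UV cone mosaic; the most posterior band
   gives the red/green mosaic.
2. **The lateral scale is unknown.** Scanners calibrated for mouse optics
   cover an actual retinal extent in a fish eye that depends on the eye's
   axial length *A*.  The scaling coefficient *s* (actual / nominal scan
   width) follows a linear law

   &nbsp;&nbsp;&nbsp;&nbsp;*s* = *b·A* + *r*,&nbsp;&nbsp; *A* in mm,

   calibrated once per instrument by pairing in vivo OCT distances (px)
   against ex vivo microscopy distances (µm) between the same blood-vessel
   branch points.  A bundled calibration (*b* = 0.2187 /mm, *r* = 0.4059,
   specific to a Bioptigen system with a mouse retina probe) converts axial
   length directly into µm/px.

On the scaled en face image, cones are detected semi-automatically (local
maxima after illumination flat-fielding, with manual corrections) and the
mosaic is quantified through its Voronoi tessellation: density over *bound*
cells only (cells wholly inside the analysis region), the percentage of
six-sided cells (the crystallinity index — a perfect hexagonal lattice of
spacing *d* has density 2/(√3 *d*²) and 100 % six-sided cells), side-count
histograms, nearest-neighbour distances, and contiguous "crystalline
patches" of six-sided cells.

A fully ground-truthed synthetic phantom generator (curved layers,
interleaved cone sub-mosaics, vessel shadows, speckle, per-B-scan breathing
jitter) makes every stage testable end to end without real scans.

## Worked example

```python
import octmosaic as om

# 1. synthetic retina: curved layers + jittered hexagonal UV cone mosaic
spec = om.PhantomSpec()          # 128 B-scans x 256 depth x 128 A-scans, 1.6 um/px
volume, truth = om.generate_volume(spec, seed=7)

# 2. en face projection of the anterior photoreceptor layer
contour = om.truth_contour(truth, layer=1, thickness_px=10)
svp = om.generate_svp(volume, contour)

# 3. cone detection and mosaic statistics
cones = om.detect_cones(svp, um_per_px=spec.um_per_px)
metrics = om.voronoi_metrics(cones)
print(f"detected cones:   {len(cones)} (truth: {len(truth.cones_px)})")
print(f"density:          {metrics.density_per_mm2:,.0f} cones/mm^2")
print(f"six-sided cells:  {metrics.percent_six_sided:.1f} % of {metrics.n_bound_cells} bound cells")
print(f"mean NN distance: {metrics.mean_nn_um:.2f} um")

# 4. physical scale for a real eye from its axial length
s = om.predict_scaling_coefficient(2.0, om.DEFAULT_MODEL)
meta = om.ScanMetadata(nominal_fov_mm=(1.2, 1.2), n_ascans=750, n_bscans=750)
um_fast, _ = om.physical_scale(s, meta)
print(f"A = 2.0 mm  ->  s = {s:.4f},  scan width {s*1200:.0f} um,  {um_fast:.3f} um/px")
```

Output:

```
detected cones:   817 (truth: 803)
density:          19,529 cones/mm^2
six-sided cells:  69.3 % of 706 bound cells
mean NN distance: 6.06 um
A = 2.0 mm  ->  s = 0.8433,  scan width 1012 um,  1.349 um/px
```

The default phantom mosaic is a 7.684 µm hexagonal lattice (ideal density
≈ 19,557 cones/mm²) with hard-core positional jitter tuned to the roughly
two-thirds six-sided regularity of the adult peripheral UV mosaic; the
pipeline recovers density within a few tenths of a percent and
six-sidedness within a few percentage points of the generator's ground
truth.

A `octmosaic` console script exposes the same pipeline from the shell
(`phantom`, `enface`, `calibrate`, `scale`, `detect`, `metrics`, and a
config-driven `run` that writes a hash-stamped manifest); see
`octmosaic --help`.

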