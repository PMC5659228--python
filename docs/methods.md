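# Methods

This note records the models, conventions, and numerical choices behind
`octmosaic`, and what the synthetic phantom does and does not establish
about real data.

## Coordinate and data conventions

Volumes are indexed `[bscan][depth][ascan]`; en face images are
`[bscan][ascan]` (row = B-scan, column = A-scan); all pixel coordinates are
0-based and depth increases away from the vitreous.  Volumes interchange as
multi-page TIFF (one page per B-scan) or raw binary, always with a JSON
sidecar carrying scan metadata; intensities are stored as 16-bit unsigned
when they fit, float32 otherwise, with the dtype recorded in the sidecar.
Cone coordinates are CSV with header `x,y`; contours are JSON
`{thickness_px, bscans: {index: [[ascan, depth], ...]}}`.  Round-trips are
lossless and tested.

## Contour-guided summed volume projection

A contour assigns each B-scan 2–15 control points `(ascan, depth)`.
Interpolation between control points is shape-preserving monotone cubic
(PCHIP) by default: it passes through every control point, never overshoots
the range spanned by neighbouring points (which would let the slab drift
into an adjacent sublamina), and is held constant beyond the first/last
point.  Linear interpolation is available by option; the choice between the
two is a convention of this package, and both are exposed.

The summation window of thickness *t* centred at depth *c* covers
`[c − t/2, c + t/2]` in voxel-edge coordinates, voxel *k* spanning
`[k − 0.5, k + 0.5]`; end voxels are weighted by fractional overlap.  This
makes the SVP continuous under sub-pixel contour translation and reduces to
a plain *t*-voxel sum at integer centres with odd *t*.  Windows are clamped
to the volume and clamped pixels flagged so statistics can exclude them.
Within the slab, intensity is *summed* (a normalised mean is available for
display only).  SVP is linear in the volume and monotone in thickness on
non-negative data; both properties are tested, and the implementation is
verified exactly against a brute-force triple-loop oracle on random
volumes.

Axial breathing motion shifts whole B-scans in depth.  The per-B-scan
offset between two B-scans is estimated by cross-correlating their mean
depth-intensity profiles with parabolic sub-peak refinement (typical error
≪ 0.1 px on phantoms with flat layer topography).  Note the estimator
measures total axial displacement; on strongly curved retinas the
layer-topography component is not separable from breathing, which is why
contours remain per-B-scan and propagation with offsets is an explicit
user action.

## Lateral scaling

The scaling coefficient is `s = (µm/px × n_ascans) / nominal width (µm)`,
a width ratio, hence independent of field of view and sampling counts.
Per eye, the µm/px ratio is the mean over ≥ 3 paired distances
(microscopy µm / OCT px); eyes are aggregated *before* fitting (one `(A, s)`
point per eye), and the model `s = b·A + r` is fitted by ordinary least
squares, reporting the Pearson correlation and the axial-length span of the
calibration.  Predictions outside that span warn as extrapolation and must
be positive.  Scaling is assumed isotropic (one coefficient per scan).  The
bundled default (`b = 0.2187 /mm`, `r = 0.4059`) is instrument-specific; its
predictions lie in the plausible band s ∈ (0.5, 1.1) across the adult
axial-length range 1.5–2.5 mm, which the tests assert as a sanity check
rather than as ground truth.

## Cone detection

The detector reconstructs a standard semi-automated local-maxima pipeline:

1. light Gaussian blur (default σ 0.3 px);
2. illumination flat-fielding: divide by a 5×5 median of the image.  The
   median suppresses both the cone spots and narrow vessel shadows, so the
   division removes multiplicative shading; without it, shadow edges pull
   centroids sideways and measurably scramble the Voronoi side counts;
3. background flattening by subtracting a Gaussian at roughly twice the
   spot radius (default σ 2 px), which decouples overlapping neighbour
   spots before peak finding;
4. regional maxima that are positive (locally brighter than surround) and
   above an intensity quantile (default 0.35);
5. intensity-ranked greedy suppression at a minimum separation (default
   1.8 px ≈ a cone radius at 1.6 µm/px), ties resolved by smaller row then
   column — output is deterministic;
6. sub-pixel refinement by an intensity-weighted 3×3 centroid, with the
   weights squared to sharpen against neighbour pull.

Defaults are tuned on the default phantom and scale with spot size; all are
exposed.  Flat-fielding assumes a non-zero background and should be
disabled (`flatfield_size=0`) for dark-background spot imagery.  Manual
corrections add points and remove the nearest existing cone within a snap
radius; removals with no match are errors listing the offending points.

## Voronoi mosaic statistics

A cell is *bound* iff all its vertices lie strictly inside the analysis
region (rectangle, optionally intersected with an annulus around the optic
nerve); only bound cells enter side counts and areas.  Density is
`n_bound / Σ bound-cell areas` (robust to edge clipping; a secondary
counts-per-window-area mode is reported alongside).  On perfect hexagonal
lattices the estimator matches 2/(√3 d²) to well under 0.5 %, and side
counts are exact (100 % six-sided on hex, 0 % on square lattices).  The
tessellation is scipy's Voronoi diagram, cross-checked cell-by-cell in the
tests against an independent half-plane-clipping oracle with a
security-radius stopping rule.  Exactly degenerate (cocircular) inputs are
perturbed by 1e-9 px before retrying; numerically collinear inputs are an
error.

Crystalline patches are this package's operationalisation of visibly
ordered regions: connected components of bound six-sided cells under
shared-Voronoi-edge adjacency, optionally grown by adjacent bound non-six
cells while the patch's six-sided fraction stays above a threshold
(default 0.9), reported with summed member-cell area in mm².  The
peripheral annulus radii (e.g. "20–50 µm from the optic nerve") are user
parameters with no default: that published definition is surprisingly small
against a >1 mm field and may reflect a transcription issue, so the package
does not bake it in.

## The synthetic phantom

The phantom emulates the features the pipeline must survive: four curved
layers (2-D quadratic centre surfaces, Gaussian axial profiles), two
interleaved photoreceptor sub-mosaics offset by half a lattice spacing (the
anterior one is "the UV layer" by convention), smooth vessel paths whose
shadows attenuate everything below the innermost layer, per-B-scan
breathing jitter (sinusoid + random walk), additive Gaussian noise, and
multiplicative speckle.  Default size is 128×256×128 at 1.6 µm/px — the
native pixel size of a 1.2 mm / 750 A-scan zebrafish scan — so geometry
statistics transfer directly while a full pipeline run takes seconds.

The default mosaic is a 7.684 µm hexagonal lattice (ideal density
2/(√3 d²) ≈ 19,557 cones/mm², the reported adult UV figure) jittered with
SD 1.5 µm under a hard-core minimum separation of 4.5 µm.  The hard core
reflects that cone somata cannot overlap; unconstrained Gaussian jitter
produces arbitrarily close pairs that no detector could resolve and that do
not occur in real mosaics.  This jitter level yields ≈ 70 % six-sided
Voronoi cells, matching the reported adult peripheral regularity
(67.6 ± 11 %).  Spot σ is 1.1 px (≈ 4 µm FWHM, a UV cone soma seen at OCT
resolution).  An optional disordered central disc (uniform hard-core points
at the lattice density) emulates the parapapillary larval-growth region.

What the phantom does *not* model: wave-optics speckle statistics (speckle
here is i.i.d. multiplicative noise), intra-frame eye motion, optical PSF
anisotropy, layer reflectivity variation across the field, and detector
saturation.  Passing phantom tests therefore demonstrates correctness of
the geometry/statistics pipeline under controlled conditions, not detection
performance on arbitrary clinical imagery.

## Problem sizes and determinism

Everything derives from one integer seed per run (`numpy`'s PCG64);
volumes, mosaics, and truth are bit-reproducible.  The test suite and the
acceptance script use reduced sizes chosen to keep full runs fast: the
lattice-density recovery uses a 500×500 px (0.64 mm²) field (≈ 12,500
cones), the SVP oracle checks 100 volumes ≤ 32³, the scaling-law recovery
uses 9 eyes × 200 replicates, and end-to-end checks use the default
128×256×128 phantom.  Enlarging any of these changes only runtime, not the
conclusions, and the closed-form anchors (lattice density, exact OLS on
collinear data) are size-independent.

## Known limitations

* Layer segmentation is manual/propagated by design; no automatic
  segmentation is included.
* The bundled scaling calibration applies only to the instrument it was
  derived on; other systems need a one-time recalibration
  (`fit_scaling_model`).
* Axial (depth) scaling is out of scope; axial length itself is an input.
* Sub-resolution mosaics (red/green, blue cones) are below what the
  default detection settings can separate at 1.6 µm/px, mirroring the
  physical resolution limit.
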