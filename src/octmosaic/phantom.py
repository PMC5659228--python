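"""Synthetic OCT retina phantoms with exact ground truth.

The phantom emulates the features of an adult zebrafish volume scan that the
analysis pipeline has to cope with, at a reduced default size so a full
pipeline run takes seconds:

* a stack of curved retinal layers, each a Gaussian axial reflectivity
  profile around a smooth 2-D polynomial centre surface;
* two photoreceptor sub-layers at distinct depths carrying laterally
  interleaved near-hexagonal bright-spot mosaics (offset by half a lattice
  spacing), emulating the anterior UV and posterior red/green cone tiers;
* optionally, a disordered central disc in the mosaic (random points at the
  same density) emulating the parapapillary larval-growth region;
* dark vessel shadows attenuating everything below smooth vessel paths in
  the innermost layer;
* per-B-scan axial breathing jitter (sinusoid plus random walk), additive
  Gaussian noise, and multiplicative speckle.

Default mosaic parameters reproduce the crystalline adult UV mosaic: lattice
spacing 7.684 µm (the spacing whose ideal hexagonal density is
2/(√3·d²) ≈ 19,557 cones/mm²) with positional jitter SD 0.9 µm (~12% of the
spacing), which yields roughly two-thirds six-sided Voronoi cells — the
regularity regime reported for adult zebrafish in vivo.

Everything is generated from a single integer seed and is bit-reproducible;
the accompanying :class:`PhantomTruth` carries exact cone centres, layer
depth maps, jitter offsets, and the physical scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .volume_io import OCTVolume, ScanMetadata
from .contour_enface import Contour, EnFaceImage
from .mosaic_quant import ConeMosaic

__all__ = [
    "LayerSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_mosaic",
    "generate_volume",
    "truth_contour",
    "svp_layer_contrast",
]


@dataclass
class LayerSpec:
    """One curved retinal layer.

    ``center_coeffs`` are coefficients of a low-order 2-D polynomial depth
    surface evaluated on normalised coordinates u, v ∈ [-1, 1]
    (u = ascan, v = bscan):
    ``depth(u, v) = c00 + c10*u + c01*v + c20*u² + c02*v² + c11*u*v``.
    ``thickness_px`` is the FWHM-like Gaussian axial extent; ``brightness``
    the peak reflectivity.
    """

    center_coeffs: tuple[float, float, float, float, float, float]
    thickness_px: float = 6.0
    brightness: float = 400.0
    has_cones: bool = False
    cone_phase: float = 0.0  # lattice offset in units of spacing

    def depth_map(self, n_bscans: int, n_ascans: int) -> np.ndarray:
        u = np.linspace(-1.0, 1.0, n_ascans)
        v = np.linspace(-1.0, 1.0, n_bscans)
        U, V = np.meshgrid(u, v)  # (n_bscans, n_ascans)
        c00, c10, c01, c20, c02, c11 = self.center_coeffs
        return c00 + c10 * U + c01 * V + c20 * U**2 + c02 * V**2 + c11 * U * V


def _default_layers() -> list[LayerSpec]:
    return [
        # inner retina (vessel-bearing), shallow
        LayerSpec(center_coeffs=(60.0, 2.0, 3.0, 14.0, 12.0, 0.0), thickness_px=8.0, brightness=350.0),
        # anterior photoreceptor tier (UV cones)
        LayerSpec(
            center_coeffs=(130.0, 3.0, 4.0, 22.0, 18.0, 2.0),
            thickness_px=5.0,
            brightness=300.0,
            has_cones=True,
            cone_phase=0.0,
        ),
        # posterior photoreceptor tier (red/green cones), interleaved half-spacing
        LayerSpec(
            center_coeffs=(150.0, 3.0, 4.0, 22.0, 18.0, 2.0),
            thickness_px=5.0,
            brightness=300.0,
            has_cones=True,
            cone_phase=0.5,
        ),
        # RPE-like bright band
        LayerSpec(center_coeffs=(175.0, 3.0, 4.0, 22.0, 18.0, 2.0), thickness_px=6.0, brightness=450.0),
    ]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic volume/mosaic generator.

    Defaults render a 128 (B-scans) × 256 (depth) × 128 (A-scans) volume at
    1.6 µm/px lateral scale — the native pixel size of a 1.2 mm / 750 A-scan
    zebrafish scan — so geometry statistics transfer directly.
    """

    n_bscans: int = 128
    depth: int = 256
    n_ascans: int = 128
    um_per_px: float = 1.6
    layers: list[LayerSpec] = field(default_factory=_default_layers)
    # cone mosaic
    cone_spacing_um: float = 7.684
    cone_jitter_um: float = 1.5
    cone_min_separation_um: float = 4.5
    cone_sigma_px: float = 1.1
    cone_amplitude: float = 500.0
    disorder_disc: Optional[tuple[float, float, float]] = None  # (cx_px, cy_px, radius_px)
    # vessels
    n_vessels: int = 3
    vessel_width_px: float = 3.0
    vessel_attenuation: float = 0.55
    # noise
    noise_sd: float = 12.0
    speckle_factor: float = 0.08
    # breathing
    breathing_amplitude_px: float = 3.0
    breathing_period_bscans: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_bscans", "depth", "n_ascans"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("um_per_px", "cone_spacing_um", "cone_sigma_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.cone_jitter_um < 0 or self.noise_sd < 0 or self.speckle_factor < 0:
            raise ValueError("noise and jitter scales must be non-negative")
        if self.cone_jitter_um > 0 and self.cone_spacing_um <= 2 * self.cone_jitter_um:
            warnings.warn(
                "cone spacing <= 2x positional jitter SD; the lattice will be "
                "nearly indistinguishable from random packing",
                stacklevel=2,
            )
        max_center = max(ls.depth_map(2, 2).max() + 3 * ls.thickness_px for ls in self.layers)
        if max_center + self.breathing_amplitude_px > self.depth:
            raise ValueError(
                f"layers (deepest extent ~{max_center:.0f} px + breathing "
                f"{self.breathing_amplitude_px} px) exceed volume depth {self.depth}"
            )

    def to_json(self, path) -> Path:
        path = Path(path)
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
        return path

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        known = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown phantom spec keys: {sorted(unknown)}")
        if "layers" in d:
            d["layers"] = [LayerSpec(**{**ls, "center_coeffs": tuple(ls["center_coeffs"])}) for ls in d["layers"]]
        if d.get("disorder_disc") is not None:
            d["disorder_disc"] = tuple(d["disorder_disc"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Exact ground truth emitted alongside a phantom.

    ``cones_px`` are (x, y) en face pixel centres of the anterior (UV-like)
    mosaic; ``cones_um`` the same in µm.  ``layer_depths`` maps layer index →
    (n_bscans, n_ascans) centre-depth map *including* breathing jitter.
    ``jitter_px`` is the per-B-scan axial offset.
    """

    cones_px: np.ndarray
    cones_um: np.ndarray
    um_per_px: float
    layer_depths: dict[int, np.ndarray] = field(default_factory=dict)
    jitter_px: np.ndarray = field(default_factory=lambda: np.zeros(0))
    vessel_paths: list[np.ndarray] = field(default_factory=list)
    cones_px_posterior: Optional[np.ndarray] = None


def _hard_core_jitter(
    base: np.ndarray,
    jitter_sd: float,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 25,
) -> np.ndarray:
    """Jitter lattice points while enforcing a minimum pairwise separation.

    Cone somata cannot overlap, so independent Gaussian jitter — which
    produces arbitrarily close pairs — is replaced by sequential jitter with
    redraws: each point keeps the first draw that stays ``min_sep`` away from
    all previously placed points (falling back to the farthest draw if none
    succeeds).  Deterministic given the generator state.
    """
    if jitter_sd <= 0:
        return base.copy()
    out = np.empty_like(base)
    # only neighbours within this radius can violate the constraint
    reach = min_sep + 8.0 * jitter_sd
    from scipy.spatial import cKDTree

    base_tree = cKDTree(base)
    neighbours = base_tree.query_ball_point(base, reach)
    for i, p in enumerate(base):
        prior = [j for j in neighbours[i] if j < i]
        prev = out[prior] if prior else None
        best = None
        best_d = -np.inf
        for _ in range(max_tries):
            cand = p + rng.normal(0.0, jitter_sd, 2)
            if prev is None:
                best = cand
                break
            d = float(np.min(np.hypot(prev[:, 0] - cand[0], prev[:, 1] - cand[1])))
            if d >= min_sep:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        out[i] = best
    return out


def _hex_lattice(width_um: float, height_um: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice points (µm) covering [0,width] x [0,height], margin-padded."""
    row_h = spacing * np.sqrt(3.0) / 2.0
    pts = []
    j = 0
    y = -spacing
    while y <= height_um + spacing:
        x0 = -spacing + (spacing / 2.0 if j % 2 else 0.0)
        xs = np.arange(x0, width_um + spacing + 1e-9, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
        j += 1
        y = -spacing + j * row_h
    return np.vstack(pts)


def generate_mosaic(spec: PhantomSpec, seed: Optional[int] = None, phase: float = 0.0):
    """Generate a jittered hexagonal cone mosaic with ground truth.

    Returns ``(ConeMosaic, PhantomTruth)``; the mosaic holds the *true*
    centres (what a perfect detector would output).  ``phase`` shifts the
    lattice by that fraction of a spacing on both axes (used for the
    interleaved posterior tier).  If ``spec.disorder_disc`` is set, lattice
    points inside the disc are replaced by uniform-random points at the same
    mean density.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    width_um = spec.n_ascans * spec.um_per_px
    height_um = spec.n_bscans * spec.um_per_px
    d = spec.cone_spacing_um

    pts = _hex_lattice(width_um, height_um, d)
    pts = pts + phase * d  # lattice phase offset (both axes)
    min_sep = min(spec.cone_min_separation_um, 0.9 * d)
    pts = _hard_core_jitter(pts, spec.cone_jitter_um, min_sep, rng)

    if spec.disorder_disc is not None:
        cx, cy, r_px = spec.disorder_disc
        c_um = np.array([cx * spec.um_per_px, cy * spec.um_per_px])
        r_um = r_px * spec.um_per_px
        inside = np.hypot(pts[:, 0] - c_um[0], pts[:, 1] - c_um[1]) < r_um
        n_replace = int(inside.sum())
        pts = pts[~inside]
        # hard-core uniform points in the disc at (up to) the lattice density
        kept: list[np.ndarray] = []
        rr = r_um * np.sqrt(rng.uniform(0, 1, 3 * n_replace))
        th = rng.uniform(0, 2 * np.pi, 3 * n_replace)
        cand_pts = np.column_stack([c_um[0] + rr * np.cos(th), c_um[1] + rr * np.sin(th)])
        for cand in cand_pts:
            if len(kept) >= n_replace:
                break
            others = np.vstack([pts] + kept) if kept else pts
            if np.min(np.hypot(others[:, 0] - cand[0], others[:, 1] - cand[1])) >= min_sep:
                kept.append(cand)
        if kept:
            pts = np.vstack([pts] + kept)

    # keep points inside the en face field (px coordinates)
    px = pts / spec.um_per_px
    keep = (
        (px[:, 0] >= 0)
        & (px[:, 0] <= spec.n_ascans - 1)
        & (px[:, 1] >= 0)
        & (px[:, 1] <= spec.n_bscans - 1)
    )
    px = px[keep]
    um = pts[keep]

    mosaic = ConeMosaic(
        points=px,
        um_per_px=spec.um_per_px,
        bounds=(0.0, 0.0, float(spec.n_ascans - 1), float(spec.n_bscans - 1)),
    )
    truth = PhantomTruth(cones_px=px.copy(), cones_um=um.copy(), um_per_px=spec.um_per_px)
    return mosaic, truth


def _spot_image(shape: tuple[int, int], centers_px: np.ndarray, sigma: float, amplitude: float) -> np.ndarray:
    """Sum of Gaussian spots rendered on a pixel grid (local patches)."""
    h, w = shape
    img = np.zeros((h, w), dtype=float)
    half = max(2, int(np.ceil(4 * sigma)))
    for x, y in centers_px:
        c0, c1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 2
        r0, r1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 2
        c0c, c1c = max(c0, 0), min(c1, w)
        r0c, r1c = max(r0, 0), min(r1, h)
        if c0c >= c1c or r0c >= r1c:
            continue
        ys = np.arange(r0c, r1c)[:, None]
        xs = np.arange(c0c, c1c)[None, :]
        img[r0c:r1c, c0c:c1c] += amplitude * np.exp(
            -((xs - x) ** 2 + (ys - y) ** 2) / (2.0 * sigma**2)
        )
    return img


def _vessel_mask(spec: PhantomSpec, rng: np.random.Generator):
    """Smooth vessel paths across the fast axis; returns (attenuation map, paths)."""
    h, w = spec.n_bscans, spec.n_ascans
    atten = np.ones((h, w), dtype=float)
    paths = []
    for _ in range(spec.n_vessels):
        y0 = rng.uniform(0.15, 0.85) * h
        amp = rng.uniform(0.05, 0.15) * h
        period = rng.uniform(1.0, 2.0) * w
        phase = rng.uniform(0, 2 * np.pi)
        xs = np.arange(w)
        ys = y0 + amp * np.sin(2 * np.pi * xs / period + phase)
        paths.append(np.column_stack([xs, ys]))
        rows = np.arange(h)[:, None]
        profile = np.exp(-((rows - ys[None, :]) ** 2) / (2.0 * (spec.vessel_width_px / 2.355) ** 2))
        atten *= 1.0 - (1.0 - spec.vessel_attenuation) * profile
    return atten, paths


def generate_volume(spec: PhantomSpec, seed: Optional[int] = None):
    """Render the full phantom OCT volume; returns ``(OCTVolume, PhantomTruth)``.

    Layer order: each layer is a Gaussian axial band around its (jittered)
    centre surface; cone-bearing layers are brightness-modulated by their
    spot mosaic; vessel shadows attenuate all layers *below* the first
    (inner) layer; additive Gaussian noise and multiplicative speckle come
    last.  Intensities are clipped at zero (detector floor).
    """
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    nb, dd, na = spec.n_bscans, spec.depth, spec.n_ascans

    # breathing jitter: sinusoid + small random walk, zero-mean
    b_idx = np.arange(nb)
    jitter = spec.breathing_amplitude_px * np.sin(2 * np.pi * b_idx / spec.breathing_period_bscans)
    walk = np.cumsum(rng.normal(0.0, 0.08 * spec.breathing_amplitude_px + 1e-12, nb))
    jitter = jitter + walk - (jitter + walk).mean() if spec.breathing_amplitude_px > 0 else np.zeros(nb)

    # cone mosaics for the cone-bearing layers (deterministic sub-seeds)
    cone_layers = [i for i, ls in enumerate(spec.layers) if ls.has_cones]
    spot_maps: dict[int, np.ndarray] = {}
    truth_cones_px = np.zeros((0, 2))
    truth_cones_um = np.zeros((0, 2))
    posterior_px = None
    for order, li in enumerate(cone_layers):
        _, t = generate_mosaic(spec, seed=base_seed + 1000 + order, phase=spec.layers[li].cone_phase)
        spot_maps[li] = _spot_image((nb, na), t.cones_px, spec.cone_sigma_px, spec.cone_amplitude)
        if order == 0:
            truth_cones_px, truth_cones_um = t.cones_px, t.cones_um
        elif posterior_px is None:
            posterior_px = t.cones_px

    atten, vessel_paths = _vessel_mask(spec, rng)

    depth_axis = np.arange(dd, dtype=float)[None, :, None]  # (1, depth, 1)
    volume = np.zeros((nb, dd, na), dtype=float)
    layer_depths: dict[int, np.ndarray] = {}
    for li, ls in enumerate(spec.layers):
        centers = ls.depth_map(nb, na) + jitter[:, None]  # (nb, na)
        layer_depths[li] = centers
        sigma_z = ls.thickness_px / 2.355  # FWHM -> sigma
        amp = np.full((nb, na), ls.brightness)
        if li in spot_maps:
            amp = amp + spot_maps[li]
        if li > 0:  # vessels sit in the innermost layer; shadows fall below it
            amp = amp * atten
        volume += amp[:, None, :] * np.exp(
            -((depth_axis - centers[:, None, :]) ** 2) / (2.0 * sigma_z**2)
        )

    if spec.speckle_factor > 0:
        volume *= 1.0 + spec.speckle_factor * rng.standard_normal(volume.shape)
    if spec.noise_sd > 0:
        volume += rng.normal(0.0, spec.noise_sd, volume.shape)
    np.clip(volume, 0.0, None, out=volume)

    meta = ScanMetadata(
        nominal_fov_mm=(na * spec.um_per_px / 1000.0, nb * spec.um_per_px / 1000.0),
        n_ascans=na,
        n_bscans=nb,
        eye_id=f"phantom-seed{base_seed}",
    )
    truth = PhantomTruth(
        cones_px=truth_cones_px,
        cones_um=truth_cones_um,
        um_per_px=spec.um_per_px,
        layer_depths=layer_depths,
        jitter_px=jitter,
        vessel_paths=vessel_paths,
        cones_px_posterior=posterior_px,
    )
    return OCTVolume(intensity=volume.astype(np.float32), meta=meta), truth


def truth_contour(truth: PhantomTruth, layer: int, thickness_px: float, n_points: int = 9) -> Contour:
    """Build the ideal contour tracking a phantom layer's true depth map.

    Samples ``n_points`` control points per B-scan from the true centre
    surface — the contour an infinitely careful operator would draw.
    """
    depths = truth.layer_depths[layer]
    nb, na = depths.shape
    cols = np.unique(np.linspace(0, na - 1, n_points).round().astype(int))
    per_bscan = {
        b: [(int(c), float(depths[b, c])) for c in cols] for b in range(nb)
    }
    return Contour(per_bscan=per_bscan, thickness_px=thickness_px)


def svp_layer_contrast(image: EnFaceImage, background_level: float, thickness_px: float) -> float:
    """Mean layer-to-background contrast of an en face projection.

    ``background_level`` is the phantom's known off-layer intensity floor per
    voxel; a slab of thickness ``t`` over pure background sums to
    ``t * background_level``, so the contrast is
    ``(mean(SVP) - t*bg) / (t*bg + eps)`` — zero for a slab that misses the
    layer everywhere, maximal for one that captures it everywhere.
    """
    t_bg = thickness_px * background_level
    return float((image.pixels.mean() - t_bg) / (t_bg + 1e-12))
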