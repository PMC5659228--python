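"""Curved per-B-scan contours and en face summed volume projections (SVPs).

The retina is curved in an OCT volume, so a flat depth slab mixes retinal
layers across the field.  A *contour* assigns each B-scan a small set of
control points (A-scan index, depth) which are interpolated into a depth
profile; summing intensity over a fixed-thickness window centred on that
profile yields an en face image of a single retinal layer.  Placing the
contour on the most anterior photoreceptor band isolates the UV cone mosaic,
on the most posterior band the red/green mosaic — layer identity is purely a
matter of contour placement.

Interpolation is shape-preserving monotone cubic (PCHIP) by default so the
profile never overshoots between control points into an adjacent layer;
linear interpolation is available via ``mode="linear"``.  Beyond the first and
last control point the profile is held constant (edge-hold).

The summation window for thickness ``t`` centred at depth ``c`` covers
``[c - t/2, c + t/2]`` in voxel-edge coordinates (voxel ``k`` spans
``[k - 0.5, k + 0.5]``); end voxels are weighted by fractional overlap, which
makes the SVP continuous under sub-pixel contour translation and reduces to a
plain ``t``-voxel sum at integer centres with odd ``t``.  Windows are clamped
to the volume and clamped pixels flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.interpolate import PchipInterpolator

from .volume_io import OCTVolume

__all__ = [
    "Contour",
    "ContourError",
    "EnFaceImage",
    "interpolate_contour",
    "edit_contour",
    "propagate_contour",
    "estimate_bscan_offset",
    "generate_svp",
    "flat_slab_svp",
    "read_contour",
    "write_contour",
]

CONTROL_POINT_SOFT_MIN = 3
CONTROL_POINT_SOFT_MAX = 15


class ContourError(ValueError):
    """A contour is missing, degenerate, or an edit would make it so."""


def _normalize_points(points) -> list[tuple[int, float]]:
    out = [(int(a), float(d)) for a, d in points]
    ascans = [a for a, _ in out]
    if len(set(ascans)) != len(ascans):
        raise ContourError(f"duplicate ascan indices in control points: {sorted(ascans)}")
    if ascans != sorted(ascans):
        out = sorted(out)
    return out


@dataclass
class Contour:
    """Per-B-scan control points plus a slab thickness.

    ``per_bscan`` maps B-scan index → ordered ``(ascan_index, depth_px)``
    control points (strictly increasing ascan index, ≥ 2 per B-scan;
    3–15 is the typical working range and values outside it warn).
    ``thickness_px`` is the full axial window thickness in pixels, typically
    10–20 for a photoreceptor sublamina.
    """

    per_bscan: dict[int, list[tuple[int, float]]] = field(default_factory=dict)
    thickness_px: float = 12

    def __post_init__(self) -> None:
        if not self.thickness_px >= 1:
            raise ContourError(f"thickness_px must be >= 1, got {self.thickness_px}")
        clean: dict[int, list[tuple[int, float]]] = {}
        for b, pts in self.per_bscan.items():
            pts = _normalize_points(pts)
            if len(pts) < 2:
                raise ContourError(f"B-scan {b}: a contour needs >= 2 control points, got {len(pts)}")
            if not (CONTROL_POINT_SOFT_MIN <= len(pts) <= CONTROL_POINT_SOFT_MAX):
                warnings.warn(
                    f"B-scan {b}: {len(pts)} control points is outside the typical "
                    f"{CONTROL_POINT_SOFT_MIN}-{CONTROL_POINT_SOFT_MAX} range",
                    stacklevel=2,
                )
            clean[int(b)] = pts
        self.per_bscan = clean

    def copy(self) -> "Contour":
        return Contour(
            per_bscan={b: list(pts) for b, pts in self.per_bscan.items()},
            thickness_px=self.thickness_px,
        )

    @classmethod
    def constant(cls, depth: float, n_bscans: int, n_ascans: int, thickness_px: float = 12) -> "Contour":
        """A flat contour at a single depth on every B-scan."""
        pts = [(0, float(depth)), (max(1, n_ascans - 1), float(depth))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return cls(per_bscan={b: list(pts) for b in range(n_bscans)}, thickness_px=thickness_px)


@dataclass
class EnFaceImage:
    """An en face image: rows = B-scans, columns = A-scans.

    ``clamped`` marks pixels whose depth window hit the top or bottom of the
    volume (their sums cover less than the full thickness).
    """

    pixels: np.ndarray
    um_per_px: Optional[float] = None
    provenance: str = "contour"
    clamped: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"en face image must be 2-D, got ndim={self.pixels.ndim}")


def interpolate_contour(control_points, n_ascans: int, mode: str = "pchip") -> np.ndarray:
    """Interpolate control points into one depth per A-scan index.

    The profile passes through every control point exactly and is held
    constant (edge-hold) beyond the first/last control point.  ``mode`` is
    ``"pchip"`` (monotone cubic, no overshoot) or ``"linear"``.
    """
    pts = _normalize_points(control_points)
    if len(pts) < 2:
        raise ContourError(f"need >= 2 control points, got {len(pts)}")
    x = np.array([a for a, _ in pts], dtype=float)
    y = np.array([d for _, d in pts], dtype=float)
    xi = np.arange(n_ascans, dtype=float)
    xi_clamped = np.clip(xi, x[0], x[-1])  # edge-hold extrapolation
    if mode == "pchip":
        profile = PchipInterpolator(x, y)(xi_clamped)
    elif mode == "linear":
        profile = np.interp(xi_clamped, x, y)
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    return np.asarray(profile, dtype=float)


def edit_contour(contour: Contour, bscan: int, action: str, point) -> Contour:
    """Return a new contour with one control point added, moved, or deleted.

    ``add`` at an existing ascan index replaces that point's depth (documented
    tie rule); ``move`` changes the depth of the point at the given ascan
    index; ``delete`` removes it.  Edits that would leave fewer than 2 points
    raise :class:`ContourError`.  Other B-scans are untouched.
    """
    bscan = int(bscan)
    pts = list(contour.per_bscan.get(bscan, []))
    a = int(point[0])
    if action in ("add", "move"):
        d = float(point[1])
        existing = [i for i, (pa, _) in enumerate(pts) if pa == a]
        if action == "move" and not existing:
            raise ContourError(f"B-scan {bscan}: no control point at ascan {a} to move")
        if existing:
            pts[existing[0]] = (a, d)
        else:
            pts.append((a, d))
    elif action == "delete":
        existing = [i for i, (pa, _) in enumerate(pts) if pa == a]
        if not existing:
            raise ContourError(f"B-scan {bscan}: no control point at ascan {a} to delete")
        if len(pts) - 1 < 2:
            raise ContourError(f"B-scan {bscan}: deleting would leave fewer than 2 control points")
        del pts[existing[0]]
    else:
        raise ValueError(f"unknown edit action {action!r}")

    new_map = {b: list(p) for b, p in contour.per_bscan.items()}
    new_map[bscan] = sorted(pts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Contour(per_bscan=new_map, thickness_px=contour.thickness_px)


def propagate_contour(contour: Contour, from_bscan: int, to_bscans, axial_offset_px=0.0) -> Contour:
    """Copy one B-scan's control points to others, depth-shifted.

    ``axial_offset_px`` may be a scalar (applied to every target) or a
    sequence aligned with ``to_bscans`` (e.g. per-B-scan breathing offsets).
    Existing target contours are overwritten; this is how a single adjusted
    contour is carried across a volume while correcting axial breathing jitter.
    """
    src = contour.per_bscan.get(int(from_bscan))
    if not src:
        raise ContourError(f"source B-scan {from_bscan} has no contour")
    targets = list(to_bscans)
    offsets = np.broadcast_to(np.asarray(axial_offset_px, dtype=float), (len(targets),))
    new_map = {b: list(p) for b, p in contour.per_bscan.items()}
    for b, off in zip(targets, offsets):
        new_map[int(b)] = [(a, d + float(off)) for a, d in src]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Contour(per_bscan=new_map, thickness_px=contour.thickness_px)


def estimate_bscan_offset(volume: OCTVolume, bscan_a: int, bscan_b: int) -> float:
    """Axial offset (px) of B-scan *b* relative to B-scan *a*.

    Cross-correlates the two B-scans' mean depth-intensity profiles and
    refines the integer-lag peak by parabolic interpolation.  A positive
    return means *b*'s structure sits deeper than *a*'s, i.e. a contour drawn
    on *a* should be shifted by the returned amount to fit *b*.
    """
    prof_a = volume.intensity[int(bscan_a)].mean(axis=1).astype(float)
    prof_b = volume.intensity[int(bscan_b)].mean(axis=1).astype(float)
    prof_a = prof_a - prof_a.mean()
    prof_b = prof_b - prof_b.mean()
    if not (prof_a.any() and prof_b.any()):
        raise ValueError("cannot estimate offset from a flat (zero-variance) depth profile")
    corr = np.correlate(prof_b, prof_a, mode="full")
    n = prof_a.size
    k = int(np.argmax(corr))
    lag = float(k - (n - 1))
    # parabolic sub-pixel refinement around the peak
    if 0 < k < corr.size - 1:
        c_m, c_0, c_p = corr[k - 1], corr[k], corr[k + 1]
        denom = c_m - 2.0 * c_0 + c_p
        if denom != 0:
            lag += 0.5 * (c_m - c_p) / denom
    return lag


def _svp_weights(center: float, thickness: float, depth_dim: int):
    """Depth-voxel weights for a window [center - t/2, center + t/2].

    Voxel k covers [k - 0.5, k + 0.5]; returns (k0, weights, clamped).
    """
    lo = center - thickness / 2.0
    hi = center + thickness / 2.0
    clamped = lo < -0.5 or hi > depth_dim - 0.5
    lo_c = max(lo, -0.5)
    hi_c = min(hi, depth_dim - 0.5)
    if hi_c <= lo_c:
        return 0, np.zeros(0), True
    k0 = int(np.floor(lo_c + 0.5))
    k1 = int(np.ceil(hi_c + 0.5)) - 1
    k1 = min(k1, depth_dim - 1)
    ks = np.arange(k0, k1 + 1)
    w = np.minimum(hi_c, ks + 0.5) - np.maximum(lo_c, ks - 0.5)
    return k0, np.clip(w, 0.0, 1.0), clamped


def generate_svp(
    volume: OCTVolume,
    contour: Contour,
    mode: str = "sum",
    interp: str = "pchip",
) -> EnFaceImage:
    """Generate an en face summed volume projection along a curved contour.

    Every B-scan must carry a contour (drawn directly or via
    :func:`propagate_contour`).  ``mode="sum"`` (default) sums intensity over
    the depth window; ``mode="mean"`` divides by the effective window weight,
    for display normalisation.
    """
    nb, depth_dim, na = volume.intensity.shape
    missing = [b for b in range(nb) if b not in contour.per_bscan]
    if missing:
        raise ContourError(f"no contour defined for B-scan(s) {missing[:8]}{'...' if len(missing) > 8 else ''}")

    t = float(contour.thickness_px)
    pixels = np.zeros((nb, na), dtype=float)
    clamped = np.zeros((nb, na), dtype=bool)
    depth_edges = np.arange(depth_dim + 1, dtype=float) - 0.5

    for b in range(nb):
        centers = interpolate_contour(contour.per_bscan[b], na, mode=interp)
        lo = np.maximum(centers - t / 2.0, -0.5)
        hi = np.minimum(centers + t / 2.0, depth_dim - 0.5)
        clamped[b] = (centers - t / 2.0 < -0.5) | (centers + t / 2.0 > depth_dim - 0.5)
        # per-voxel overlap weights, vectorised over (depth, ascan)
        ov = np.minimum(hi[None, :], depth_edges[1:, None]) - np.maximum(lo[None, :], depth_edges[:-1, None])
        w = np.clip(ov, 0.0, 1.0)
        sums = np.einsum("da,da->a", volume.intensity[b].astype(float), w)
        if mode == "mean":
            tot = w.sum(axis=0)
            sums = np.divide(sums, tot, out=np.zeros_like(sums), where=tot > 0)
        elif mode != "sum":
            raise ValueError(f"unknown SVP mode {mode!r}")
        pixels[b] = sums

    return EnFaceImage(pixels=pixels, provenance=f"contour(thickness={t:g},mode={mode})", clamped=clamped)


def flat_slab_svp(volume: OCTVolume, depth: float, thickness_px: float, mode: str = "sum") -> EnFaceImage:
    """En face projection over a flat slab — the vendor-software baseline.

    Equivalent to :func:`generate_svp` with a constant contour at ``depth``;
    on a curved retina this mixes layers across the field, which is the
    failure mode the curved contour exists to fix.
    """
    nb, depth_dim, na = volume.intensity.shape
    if not (-0.5 <= depth <= depth_dim - 0.5):
        raise ValueError(f"slab depth {depth} outside volume depth range [0, {depth_dim - 1}]")
    contour = Contour.constant(depth, nb, na, thickness_px=thickness_px)
    img = generate_svp(volume, contour, mode=mode)
    img.provenance = f"flat_slab(depth={depth:g},thickness={thickness_px:g},mode={mode})"
    return img


def write_contour(contour: Contour, path) -> Path:
    """Serialise a contour to JSON: ``{thickness_px, bscans: {index: [[ascan, depth], ...]}}``."""
    path = Path(path)
    payload = {
        "thickness_px": contour.thickness_px,
        "bscans": {str(b): [[a, d] for a, d in pts] for b, pts in sorted(contour.per_bscan.items())},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def read_contour(path) -> Contour:
    """Read a contour from the JSON layout written by :func:`write_contour`."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        per_bscan = {int(b): [(int(a), float(d)) for a, d in pts] for b, pts in payload["bscans"].items()}
        thickness = payload["thickness_px"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ContourError(f"malformed contour JSON {path}: {exc}") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return Contour(per_bscan=per_bscan, thickness_px=thickness)
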