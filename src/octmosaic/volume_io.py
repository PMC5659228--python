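"""Open-format I/O for OCT volumes, en face images, contours, and cone coordinates.

Vendor OCT containers are proprietary; this package defines an open interchange
layout instead:

* **Volume**: multi-page TIFF, one page per B-scan, page rows = depth, page
  columns = A-scans, plus a JSON sidecar (``<stem>.json``) carrying scan
  metadata.  A headerless raw-binary layout (C-order ``[bscan][depth][ascan]``)
  with the same sidecar is also supported.
* **Coordinates**: CSV with header ``x,y`` in en face pixel units
  (x = A-scan column, y = B-scan row).
* **Contours**: JSON (see :mod:`octmosaic.contour_enface`).

Axis convention, used everywhere in the package: volumes are indexed
``[bscan][depth][ascan]`` and en face images ``[bscan][ascan]``; all pixel
coordinates are 0-based; depth increases away from the vitreous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ScanMetadata",
    "OCTVolume",
    "MetadataError",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_coordinates",
    "write_coordinates",
    "read_enface",
    "write_enface",
]

SIDECAR_SCHEMA_VERSION = 1


class MetadataError(ValueError):
    """Sidecar metadata is missing, malformed, or self-contradictory."""


class FormatError(ValueError):
    """File contents contradict the declared metadata (e.g. dimension mismatch)."""


@dataclass
class ScanMetadata:
    """Acquisition metadata for one OCT volume scan.

    Parameters
    ----------
    nominal_fov_mm
        Nominal field of view (fast-axis, slow-axis) in mm, as programmed on
        the scanner.  The *actual* retinal extent differs by the eye's
        magnification; see :mod:`octmosaic.scaling`.
    n_ascans, n_bscans
        Lateral sampling: A-scans per B-scan and number of B-scans.
    axial_pixel_um
        Depth sampling in µm/px, if known.
    eye_id
        Free-text identifier of the imaged eye.
    axial_length_mm
        Axial length of the eye in mm, if measured (input to lateral scaling).
    """

    nominal_fov_mm: tuple[float, float] = (1.2, 1.2)
    n_ascans: int = 750
    n_bscans: int = 750
    axial_pixel_um: Optional[float] = None
    eye_id: str = ""
    axial_length_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.nominal_fov_mm = (float(self.nominal_fov_mm[0]), float(self.nominal_fov_mm[1]))
        if self.nominal_fov_mm[0] <= 0 or self.nominal_fov_mm[1] <= 0:
            raise MetadataError(f"nominal_fov_mm must be positive, got {self.nominal_fov_mm}")
        self.n_ascans = int(self.n_ascans)
        self.n_bscans = int(self.n_bscans)
        if self.n_ascans <= 0 or self.n_bscans <= 0:
            raise MetadataError(
                f"scan counts must be positive, got n_ascans={self.n_ascans}, n_bscans={self.n_bscans}"
            )
        for name in ("axial_pixel_um", "axial_length_mm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise MetadataError(f"{name} must be positive if given, got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nominal_fov_mm"] = list(self.nominal_fov_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMetadata":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise MetadataError(f"unknown metadata keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:  # missing required key
            raise MetadataError(str(exc)) from exc


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with metadata.

    ``intensity`` is indexed ``[bscan][depth][ascan]`` and must be finite and
    non-negative; ``meta.n_bscans``/``meta.n_ascans`` must match the array.
    """

    intensity: np.ndarray
    meta: ScanMetadata = field(default_factory=ScanMetadata)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise FormatError(f"volume must be 3-D [bscan][depth][ascan], got ndim={self.intensity.ndim}")
        if min(self.intensity.shape) < 1:
            raise FormatError(f"all volume dimensions must be >= 1, got shape {self.intensity.shape}")
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("volume intensities must be finite")
        if np.any(self.intensity < 0):
            raise FormatError("volume intensities must be non-negative")
        nb, _, na = self.intensity.shape
        if self.meta.n_bscans != nb or self.meta.n_ascans != na:
            raise FormatError(
                f"metadata says {self.meta.n_bscans} B-scans x {self.meta.n_ascans} A-scans, "
                f"file has {nb} x {na}"
            )

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[0]

    @property
    def depth(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.intensity.shape[2]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing sidecar metadata file: {sidecar}")
    with open(sidecar) as fh:
        payload = json.load(fh)
    if payload.get("schema_version", SIDECAR_SCHEMA_VERSION) > SIDECAR_SCHEMA_VERSION:
        raise MetadataError(f"sidecar schema_version {payload['schema_version']} is newer than supported")
    return payload


def read_volume(path, layout: str = "tiff_stack", meta: Optional[ScanMetadata] = None) -> OCTVolume:
    """Read an OCT volume from the open interchange layout.

    Parameters
    ----------
    path
        The volume file (``.tiff`` stack or raw binary).
    layout
        ``"tiff_stack"`` (default) or ``"raw_binary"``.
    meta
        Metadata to use instead of the JSON sidecar (the sidecar is then
        optional for TIFF; raw binary always needs shape/dtype from a sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if layout == "tiff_stack":
        arr = tifffile.imread(path)
        if arr.ndim == 2:  # single-page stack
            arr = arr[None, :, :]
        if meta is None:
            payload = _load_sidecar(path)
            meta = ScanMetadata.from_dict(payload.get("metadata", {}))
    elif layout == "raw_binary":
        payload = _load_sidecar(path)
        if meta is None:
            meta = ScanMetadata.from_dict(payload.get("metadata", {}))
        try:
            shape = tuple(payload["shape"])
            dtype = np.dtype(payload["dtype"])
        except KeyError as exc:
            raise MetadataError(f"raw_binary sidecar must declare {exc}") from exc
        data = np.fromfile(path, dtype=dtype)
        if data.size != int(np.prod(shape)):
            raise FormatError(f"raw file holds {data.size} voxels, sidecar shape {shape} needs {int(np.prod(shape))}")
        arr = data.reshape(shape)
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'tiff_stack' or 'raw_binary'")

    return OCTVolume(intensity=arr, meta=meta)


def write_volume(volume: OCTVolume, path, layout: str = "tiff_stack") -> Path:
    """Write a volume losslessly; the inverse of :func:`read_volume`.

    Integer volumes are stored as 16-bit unsigned when they fit; float data is
    stored as float32 with the dtype recorded in the sidecar.
    """
    path = Path(path)
    arr = volume.intensity
    if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= np.iinfo(np.uint16).max:
        arr = arr.astype(np.uint16)
    elif not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32)

    if layout == "tiff_stack":
        tifffile.imwrite(path, arr, photometric="minisblack")
    elif layout == "raw_binary":
        arr.tofile(path)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    payload = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "metadata": volume.meta.to_dict(),
        "shape": list(arr.shape),
        "dtype": arr.dtype.name,
        "layout": layout,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def read_coordinates(path) -> np.ndarray:
    """Read cone coordinates from a CSV with header ``x,y`` → ``(N, 2)`` float array."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed coordinate CSV {path}: {exc}") from exc
    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"coordinate CSV {path} must have columns x,y; got {list(df.columns)}")
    pts = np.column_stack(
        [pd.to_numeric(df["x"], errors="coerce"), pd.to_numeric(df["y"], errors="coerce")]
    ).astype(float)
    if pts.size and not np.all(np.isfinite(pts)):
        bad = int(np.flatnonzero(~np.isfinite(pts).all(axis=1))[0])
        raise FormatError(f"non-numeric or missing coordinate at data row {bad} of {path}")
    return pts.reshape(-1, 2)


def write_coordinates(points, path) -> Path:
    """Write an ``(N, 2)`` point array to CSV with header ``x,y``."""
    path = Path(path)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pd.DataFrame(pts, columns=["x", "y"]).to_csv(path, index=False)
    return path


def read_enface(path) -> tuple[np.ndarray, Optional[float]]:
    """Read an en face image (TIFF/PNG); returns ``(pixels, um_per_px)``.

    ``um_per_px`` comes from the JSON sidecar when present, else ``None``.
    """
    path = Path(path)
    import imageio.v3 as iio

    pixels = np.asarray(iio.imread(path), dtype=float)
    um_per_px = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            um_per_px = json.load(fh).get("um_per_px")
    return pixels, um_per_px


def write_enface(pixels: np.ndarray, path, um_per_px: Optional[float] = None) -> Path:
    """Write an en face image as 16-bit TIFF (rescaled to full range) + sidecar.

    The sidecar records ``um_per_px`` and the linear rescaling applied, so the
    quantitative sums remain recoverable.
    """
    path = Path(path)
    pix = np.asarray(pixels, dtype=float)
    lo, hi = float(pix.min(initial=0.0)), float(pix.max(initial=0.0))
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    encoded = np.round((pix - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, encoded, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {
                "schema_version": SIDECAR_SCHEMA_VERSION,
                "um_per_px": um_per_px,
                "encode_offset": lo,
                "encode_scale": scale,
            },
            fh,
            indent=1,
        )
    return path
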