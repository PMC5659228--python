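"""Lateral scaling of zebrafish OCT images from axial length.

An OCT scanner programmed for a nominal field of view (e.g. 1.2 mm with mouse
optics) actually covers a retinal extent that depends on the imaged eye's
magnification, hence on its axial length ``A``.  The *scaling coefficient*

    s = actual scan width / nominal scan width

is modelled as a linear function of axial length,

    s = b * A + r,        A in mm,

calibrated once per instrument by pairing in vivo OCT distances (pixels)
against ex vivo fluorescence-microscopy distances (µm) between the same
blood-vessel branch points.  The bundled default coefficients
``b = 0.2187 /mm`` and ``r = 0.4059`` are specific to the instrument they
were calibrated on (a Bioptigen system with a mouse retina probe); a new
instrument needs a one-time recalibration via :func:`fit_scaling_model`.

Because s is a width *ratio*, it is independent of the field of view and of
the A-scan/B-scan sampling counts.  Scaling is assumed isotropic: the same s
applies to the fast and slow axes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import ScanMetadata

__all__ = [
    "ScalingModel",
    "CalibrationMeasurement",
    "DEFAULT_MODEL",
    "eye_um_per_px",
    "scaling_coefficient_from_eye",
    "predict_scaling_coefficient",
    "fit_scaling_model",
    "physical_scale",
    "read_calibration_csv",
    "write_model",
    "read_model",
]


@dataclass
class ScalingModel:
    """Linear scaling-coefficient model ``s = b*A + r``.

    ``b`` is the slope in 1/mm, ``r`` the dimensionless intercept.
    ``pearson_r``/``n_eyes`` describe the calibration fit when fitted;
    ``a_min``/``a_max`` bound the axial-length range the calibration covered
    (predictions outside it warn as extrapolation).
    """

    b: float
    r: float
    pearson_r: Optional[float] = None
    n_eyes: Optional[int] = None
    a_min: Optional[float] = None
    a_max: Optional[float] = None

    def predict(self, axial_length_mm: float) -> float:
        return predict_scaling_coefficient(axial_length_mm, self)


#: Instrument-specific default calibration (Bioptigen + mouse retina probe).
DEFAULT_MODEL = ScalingModel(b=0.2187, r=0.4059)


@dataclass
class CalibrationMeasurement:
    """Paired in vivo / ex vivo distance measurements for one eye.

    ``pairs`` holds (oct_px, microscopy_um) distances between the same
    blood-vessel branch points measured on the en face OCT image and on the
    ex vivo microscopy image.  At least three pairs per eye are expected
    (fewer warns).  ``nominal_fov_um`` and ``n_ascans`` describe the scan the
    OCT distances were measured on.
    """

    eye_id: str
    axial_length_mm: float
    pairs: list[tuple[float, float]]
    nominal_fov_um: float = 1200.0
    n_ascans: int = 750

    def __post_init__(self) -> None:
        if not self.axial_length_mm > 0:
            raise ValueError(f"axial_length_mm must be positive, got {self.axial_length_mm}")
        if not self.nominal_fov_um > 0 or not self.n_ascans > 0:
            raise ValueError("nominal_fov_um and n_ascans must be positive")
        self.pairs = [(float(px), float(um)) for px, um in self.pairs]
        for px, um in self.pairs:
            if px <= 0:
                raise ValueError(f"eye {self.eye_id}: OCT pixel distance must be > 0, got {px}")
            if um <= 0:
                raise ValueError(f"eye {self.eye_id}: microscopy distance must be > 0, got {um}")
        if len(self.pairs) < 3:
            warnings.warn(
                f"eye {self.eye_id}: only {len(self.pairs)} measurement pair(s); "
                "at least three per eye are recommended",
                stacklevel=2,
            )


def eye_um_per_px(m: CalibrationMeasurement) -> tuple[float, float]:
    """Mean and SD of the per-pair µm/px ratio for one eye.

    Each pair's ratio microscopy_um / oct_px estimates the physical size of an
    en face pixel; pairs are averaged per eye before any model fitting.
    """
    ratios = np.array([um / px for px, um in m.pairs], dtype=float)
    return float(ratios.mean()), float(ratios.std(ddof=0))


def scaling_coefficient_from_eye(m: CalibrationMeasurement) -> float:
    """Scaling coefficient s = (µm/px × n_ascans) / nominal scan width (µm).

    µm/px × n_ascans is the actual scan width in µm; dividing by the nominal
    width gives the dimensionless ratio s, independent of sampling counts.
    """
    upp, _ = eye_um_per_px(m)
    return upp * m.n_ascans / m.nominal_fov_um


def predict_scaling_coefficient(axial_length_mm: float, model: ScalingModel = DEFAULT_MODEL) -> float:
    """Predicted s = b·A + r for an eye of the given axial length (mm)."""
    A = float(axial_length_mm)
    if A < 0:
        raise ValueError(f"axial length must be non-negative, got {A}")
    if model.a_min is not None and model.a_max is not None and not (model.a_min <= A <= model.a_max):
        warnings.warn(
            f"axial length {A} mm outside the calibration range "
            f"[{model.a_min}, {model.a_max}] mm; extrapolating",
            stacklevel=2,
        )
    s = model.b * A + model.r
    if not s > 0:
        raise ValueError(f"model predicts non-positive scaling coefficient s={s} at A={A} mm")
    return s


def fit_scaling_model(eyes: list[CalibrationMeasurement]) -> ScalingModel:
    """Ordinary least squares of per-eye scaling coefficient on axial length.

    Each eye contributes one (A, s) point — its measurement pairs are averaged
    first — and the fit returns slope ``b``, intercept ``r``, the Pearson
    correlation of the points, and the axial-length validity range.
    """
    if len(eyes) < 3:
        raise ValueError(f"need >= 3 calibration eyes, got {len(eyes)}")
    A = np.array([m.axial_length_mm for m in eyes], dtype=float)
    s = np.array([scaling_coefficient_from_eye(m) for m in eyes], dtype=float)
    if np.ptp(A) == 0:
        raise ValueError("all axial lengths are equal; the linear fit is singular")
    res = stats.linregress(A, s)
    pearson = float(res.rvalue)
    if not math.isfinite(pearson):  # zero variance in s (perfectly flat)
        pearson = 0.0
    return ScalingModel(
        b=float(res.slope),
        r=float(res.intercept),
        pearson_r=pearson,
        n_eyes=len(eyes),
        a_min=float(A.min()),
        a_max=float(A.max()),
    )


def physical_scale(s: float, meta: ScanMetadata) -> tuple[float, float]:
    """Physical pixel size (µm/px) on the fast and slow axes for a scan.

    The actual scan width is s × nominal width; dividing by the sampling count
    on each axis gives µm/px.  Returns (fast µm/px, slow µm/px).
    """
    if not s > 0:
        raise ValueError(f"scaling coefficient must be positive, got {s}")
    fast_um = s * meta.nominal_fov_mm[0] * 1000.0
    slow_um = s * meta.nominal_fov_mm[1] * 1000.0
    return fast_um / meta.n_ascans, slow_um / meta.n_bscans


def read_calibration_csv(path) -> list[CalibrationMeasurement]:
    """Read calibration pairs from CSV.

    Columns: ``eye_id, axial_length_mm, oct_px, microscopy_um`` (one row per
    measurement pair) and optional ``nominal_fov_um``, ``n_ascans``.
    """
    df = pd.read_csv(path)
    required = {"eye_id", "axial_length_mm", "oct_px", "microscopy_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV {path} missing columns {sorted(missing)}")
    eyes = []
    for eye_id, grp in df.groupby("eye_id", sort=True):
        kwargs = {}
        if "nominal_fov_um" in grp.columns:
            kwargs["nominal_fov_um"] = float(grp["nominal_fov_um"].iloc[0])
        if "n_ascans" in grp.columns:
            kwargs["n_ascans"] = int(grp["n_ascans"].iloc[0])
        eyes.append(
            CalibrationMeasurement(
                eye_id=str(eye_id),
                axial_length_mm=float(grp["axial_length_mm"].iloc[0]),
                pairs=list(zip(grp["oct_px"].astype(float), grp["microscopy_um"].astype(float))),
                **kwargs,
            )
        )
    return eyes


def write_model(model: ScalingModel, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "b": model.b,
                "r": model.r,
                "pearson_r": model.pearson_r,
                "n_eyes": model.n_eyes,
                "a_min": model.a_min,
                "a_max": model.a_max,
            },
            fh,
            indent=1,
        )
    return path


def read_model(path) -> ScalingModel:
    with open(path) as fh:
        d = json.load(fh)
    return ScalingModel(**{k: d.get(k) for k in ("b", "r", "pearson_r", "n_eyes", "a_min", "a_max")})
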