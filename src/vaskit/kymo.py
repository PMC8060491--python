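"""Kymograph construction and normalization.

A kymograph resamples a time-lapse stack along a vessel center-line ROI:
one row per frame, one column per unit of arc length along the polyline,
averaged across the ROI thickness perpendicular to the line.  Before
velocimetry the kymograph is background-subtracted with a per-column
rolling temporal average (default window 20 frames, matching the
acquisition workflow of ~8.55 fps recordings) and standardized to global
mean 0, standard deviation 1.  The rolling average removes the vertical
stripes produced by immobile objects and static intensity variation along
the vessel while leaving the sloped streaks of advected blood cells intact.

Conventions: 0-based coordinates, (time, y, x) array ordering, pixel
centers at integer coordinates, ROI points as (x, y).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import BoundsError, DegenerateInputError, GeometryError, ParameterError, StateError

__all__ = [
    "TimeLapseStack",
    "LineRoi",
    "Kymograph",
    "extract_kymograph",
    "normalize_kymograph",
]

#: ROI thickness used in the reference workflow (µm).
DEFAULT_ROI_THICKNESS_UM = 3.0
#: Rolling-average window for background subtraction (frames).
DEFAULT_BACKGROUND_WINDOW = 20


@dataclass(frozen=True)
class TimeLapseStack:
    """Calibrated single-channel (time, y, x) intensity volume."""

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ParameterError(f"frames must be (time, y, x); got ndim={frames.ndim}")
        if frames.shape[0] < 2:
            raise ParameterError("need at least 2 frames")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("calibration values must be positive")
        if not np.all(np.isfinite(frames)):
            raise ParameterError("intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def min_projection(self) -> np.ndarray:
        """Per-pixel minimum over time; the lumen darkens wherever a blood
        cell passed, outlining the vessel for diameter measurement."""
        return self.frames.min(axis=0)


@dataclass(frozen=True)
class LineRoi:
    """Polyline ROI in pixel coordinates.

    ``kind`` is ``"axial"`` for a center line (kymograph extraction) or
    ``"cross"`` for a line drawn across the vessel (diameter measurement).
    """

    points: np.ndarray  # (N, 2) as (x, y)
    thickness_um: float = DEFAULT_ROI_THICKNESS_UM
    kind: str = "axial"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise GeometryError("ROI needs at least two (x, y) points")
        if self.thickness_um <= 0:
            raise ParameterError("ROI thickness must be positive")
        if self.kind not in ("axial", "cross"):
            raise ParameterError(f"unknown ROI kind: {self.kind!r}")

    def arc_length_px(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class Kymograph:
    """Time (rows) × axial position (columns) matrix with calibration."""

    values: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ParameterError("kymograph must be 2D with >= 2 rows and columns")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("calibration values must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]


def _resample_polyline(points: np.ndarray, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc length; returns positions (M, 2)
    and unit normals (M, 2), both as (x, y)."""
    d = np.diff(points, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    if np.any(seg == 0):
        points = points[np.concatenate([[True], seg > 0])]
        d = np.diff(points, axis=0)
        seg = np.hypot(d[:, 0], d[:, 1])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < step:
        raise GeometryError("ROI shorter than one sampling step")
    u = np.arange(0.0, total + 1e-9, step)
    x = np.interp(u, s, points[:, 0])
    y = np.interp(u, s, points[:, 1])
    pos = np.column_stack([x, y])
    tx = np.gradient(x)
    ty = np.gradient(y)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    # normal = tangent rotated 90 degrees
    normals = np.column_stack([-ty / norm, tx / norm])
    return pos, normals


def sample_profile(image: np.ndarray, roi: LineRoi, pixel_size_um: float) -> np.ndarray:
    """Bilinear intensity profile along an ROI polyline, averaged across
    the ROI thickness, at 1-px arc-length steps."""
    pos, normals = _resample_polyline(roi.points)
    _check_bounds(image.shape, roi.points)
    thickness_px = roi.thickness_um / pixel_size_um
    half = int(np.floor(thickness_px / 2.0))
    offsets = np.arange(-half, half + 1, dtype=float)  # 1-px steps within ±thickness/2
    # coords: (n_offsets, n_samples, 2)
    xy = pos[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    coords = np.stack([xy[..., 1].ravel(), xy[..., 0].ravel()])  # (row=y, col=x)
    vals = map_coordinates(image, coords, order=1, mode="nearest")
    return vals.reshape(offsets.size, pos.shape[0]).mean(axis=0)


def _check_bounds(shape: tuple[int, int], points: np.ndarray) -> None:
    h, w = shape
    x, y = points[:, 0], points[:, 1]
    if np.any(x < 0) or np.any(y < 0) or np.any(x > w - 1) or np.any(y > h - 1):
        raise BoundsError("ROI points fall outside the image")


def extract_kymograph(stack: TimeLapseStack, roi: LineRoi) -> Kymograph:
    """Build a raw kymograph from a stack along an axial center-line ROI.

    One row per frame; each column is the bilinearly interpolated intensity
    at unit arc-length steps along the polyline, averaged across the ROI
    thickness along the local normal.  Calibration is copied from the stack.
    """
    if roi.kind != "axial":
        raise ParameterError("kymograph extraction needs an axial (center-line) ROI")
    _check_bounds(stack.frames.shape[1:], roi.points)
    pos, normals = _resample_polyline(roi.points)
    if pos.shape[0] < 2:
        raise GeometryError("fewer than 2 sample positions along the ROI")
    thickness_px = roi.thickness_um / stack.pixel_size_um
    half = int(np.floor(thickness_px / 2.0))
    offsets = np.arange(-half, half + 1, dtype=float)
    xy = pos[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    coords = np.stack([xy[..., 1].ravel(), xy[..., 0].ravel()])
    rows = np.empty((stack.n_frames, pos.shape[0]), dtype=float)
    for t in range(stack.n_frames):
        vals = map_coordinates(stack.frames[t], coords, order=1, mode="nearest")
        rows[t] = vals.reshape(offsets.size, pos.shape[0]).mean(axis=0)
    return Kymograph(
        values=rows,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        normalized=False,
    )


def _rolling_mean_truncated(values: np.ndarray, window: int) -> np.ndarray:
    """Per-column rolling temporal mean with a symmetric window that
    shrinks at the first/last frames instead of padding."""
    t = values.shape[0]
    lo = (window - 1) // 2
    hi = window // 2
    csum = np.cumsum(values, axis=0)
    csum = np.vstack([np.zeros((1, values.shape[1])), csum])
    start = np.maximum(np.arange(t) - lo, 0)
    stop = np.minimum(np.arange(t) + hi + 1, t)
    sums = csum[stop] - csum[start]
    counts = (stop - start).astype(float)[:, None]
    return sums / counts


def _standardize(values: np.ndarray) -> np.ndarray:
    std = values.std()
    if std == 0:
        raise DegenerateInputError("zero variance after background subtraction")
    return (values - values.mean()) / std


def normalize_kymograph(kymo: Kymograph, window_frames: int = DEFAULT_BACKGROUND_WINDOW) -> Kymograph:
    """Background-subtract and standardize a raw kymograph.

    Each position column has its rolling temporal average subtracted
    (removing immobile-object stripes and static background), then the whole
    matrix is normalized to global mean 0 and standard deviation 1.
    """
    if kymo.normalized:
        raise StateError("kymograph is already normalized")
    if window_frames < 1:
        raise ParameterError("window_frames must be >= 1")
    background = _rolling_mean_truncated(kymo.values, window_frames)
    out = _standardize(kymo.values - background)
    return replace(kymo, values=out, normalized=True)
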