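"""Vessel diameter, volumetric flow and the branching-exponent fit.

Diameter is measured on a minimal projection (per-pixel minimum over time),
where the lumen is darker than the surrounding tunic because blood cells
darken every lumen pixel at some frame.  The profile along a cross-vessel
line is reduced to a full width at half minimum, which is invariant to
affine intensity transforms of the projection.

Volumetric flow combines the per-vessel maximum flow speed with the
diameter under a velocity-profile model: plug flow Q = v·πd²/4 or Poiseuille
Q = (v/2)·πd²/4 (v is then the centerline maximum of a parabolic profile).
Across a vascular bed, log Q against log d follows a power law whose slope
is the branching exponent n; Murray's law predicts n = 3.  The fit is
ordinary least squares on logs, so the plug/Poiseuille prefactor only moves
the intercept, never the exponent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import FitError, MeasurementError, ParameterError
from .kymo import LineRoi, sample_profile
from .stats import GroupComparison, OlsFit, compare_groups, ols_loglog

__all__ = [
    "VesselRecord",
    "BranchingFit",
    "measure_diameter",
    "volumetric_flow",
    "fit_branching_exponent",
    "compare_diameter_groups",
    "compare_velocity_groups",
]

PROFILE_MODELS = ("plug", "poiseuille")


@dataclass(frozen=True)
class VesselRecord:
    """One vessel's measurements: diameter d (µm), maximum flow speed v
    (µm/s) and volumetric flow rate Q (µm³/s)."""

    vessel_id: str
    diameter_um: float
    v_max_um_s: float
    q_flow_um3_s: float
    age_group: str = ""

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ParameterError("diameter must be positive")
        if self.v_max_um_s < 0:
            raise ParameterError("maximum flow speed cannot be negative")


@dataclass(frozen=True)
class BranchingFit:
    """Result of the log-log power-law fit of Q against d."""

    exponent: float
    intercept: float
    exponent_stderr: float
    r_squared: float
    n_vessels: int


def measure_diameter(
    min_projection: np.ndarray,
    cross_roi: LineRoi,
    pixel_size_um: float,
    method: str = "fwhm",
) -> float:
    """Vessel diameter (µm) from a line drawn across the vessel.

    ``method="fwhm"``: full width at half minimum of the intensity profile
    along the line (the vessel is darker than the background in a minimal
    projection).  ``method="endpoints"``: plain polyline length — the fully
    manual ruler measurement.
    """
    if cross_roi.kind != "cross":
        raise ParameterError("diameter measurement needs a cross ROI")
    if pixel_size_um <= 0:
        raise ParameterError("pixel size must be positive")
    if method == "endpoints":
        return cross_roi.arc_length_px() * pixel_size_um
    if method != "fwhm":
        raise ParameterError(f"unknown diameter method: {method!r}")

    raw = sample_profile(np.asarray(min_projection, dtype=float), cross_roi, pixel_size_um)
    if raw.size < 5:
        raise MeasurementError("cross profile too short")
    # light smoothing so overlapping-cell dips inside the lumen do not
    # masquerade as the vessel floor; linear, so affine invariance holds
    kernel = np.ones(3) / 3.0
    profile = np.convolve(raw, kernel, mode="same")
    profile[0], profile[-1] = raw[0], raw[-1]
    lo, hi = float(profile.min()), float(profile.max())
    if hi - lo <= 0:
        raise MeasurementError("flat intensity profile; no vessel crossing found")
    # half level between the background plateau and the *typical* lumen
    # floor (median of the dark half) — the absolute minimum is biased by
    # spots where several dark cells overlapped
    floor = float(np.median(profile[profile < 0.5 * (lo + hi)]))
    level = 0.5 * (hi + floor)
    below = profile < level
    if below[0] or below[-1] or not below.any():
        raise MeasurementError("profile lacks two half-level crossings")
    # outermost crossings: scan inward from each end; interior structure
    # (stacked dark cells) does not move the measured edges
    left = int(np.argmax(below))  # first True
    right = profile.size - 1 - int(np.argmax(below[::-1]))  # last True

    def _cross(i_out: int, i_in: int) -> float:
        p0, p1 = profile[i_out], profile[i_in]
        return i_out + (level - p0) / (p1 - p0) * (i_in - i_out)

    x_left = _cross(left - 1, left)
    x_right = _cross(right + 1, right)
    return float((x_right - x_left) * pixel_size_um)


def volumetric_flow(v_max_um_s: float, diameter_um: float, profile_model: str = "plug") -> float:
    """Volumetric flow rate Q (µm³/s) from maximum flow speed and diameter.

    plug: Q = v·πd²/4.  poiseuille: the measured v is the centerline maximum
    of a parabolic profile whose mean is v/2, so Q = (v/2)·πd²/4.
    """
    if profile_model not in PROFILE_MODELS:
        raise ParameterError(f"unknown profile model: {profile_model!r}")
    if diameter_um <= 0:
        raise ParameterError("diameter must be positive")
    if v_max_um_s < 0:
        raise ParameterError("speed cannot be negative")
    area = math.pi * diameter_um**2 / 4.0
    q = v_max_um_s * area
    return q / 2.0 if profile_model == "poiseuille" else q


def fit_branching_exponent(records) -> BranchingFit:
    """Fit log Q on log d across vessels; the slope is the branching exponent.

    Records with non-positive d or Q are dropped with a warning; at least
    three usable records are required.
    """
    recs = list(records)
    usable = [r for r in recs if r.diameter_um > 0 and r.q_flow_um3_s > 0]
    if len(usable) < len(recs):
        warnings.warn(
            f"dropped {len(recs) - len(usable)} record(s) with non-positive d or Q",
            stacklevel=2,
        )
    if len(usable) < 3:
        raise FitError(f"need >= 3 usable vessels for the fit, got {len(usable)}")
    d = np.array([r.diameter_um for r in usable])
    q = np.array([r.q_flow_um3_s for r in usable])
    fit: OlsFit = ols_loglog(d, q)
    return BranchingFit(
        exponent=fit.slope,
        intercept=fit.intercept,
        exponent_stderr=fit.slope_stderr,
        r_squared=fit.r_squared,
        n_vessels=fit.n,
    )


def _band_filter(records, diameter_band):
    if diameter_band is None:
        return list(records)
    lo, hi = diameter_band
    return [r for r in records if lo <= r.diameter_um < hi]  # closed-open [lo, hi)


def compare_diameter_groups(
    young,
    old,
    variance_assumption: str = "pooled",
) -> GroupComparison:
    """Two-sample two-tailed t comparison of vessel diameters between groups."""
    a = [r.diameter_um for r in young]
    b = [r.diameter_um for r in old]
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 records")
    return compare_groups(
        a, b, names=("young", "old"), metric="diameter_um", variance_assumption=variance_assumption
    )


def compare_velocity_groups(
    young,
    old,
    diameter_band: tuple[float, float] | None = None,
    variance_assumption: str = "pooled",
) -> GroupComparison:
    """Compare maximum flow speeds between groups, optionally restricted to
    vessels with diameter in ``[lo, hi)`` so similar calibers are compared."""
    ya = _band_filter(young, diameter_band)
    ob = _band_filter(old, diameter_band)
    if len(ya) < 2 or len(ob) < 2:
        raise MeasurementError("diameter band leaves fewer than 2 vessels in a group")
    return compare_groups(
        [r.v_max_um_s for r in ya],
        [r.v_max_um_s for r in ob],
        names=("young", "old"),
        metric="v_max_um_s",
        variance_assumption=variance_assumption,
    )
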