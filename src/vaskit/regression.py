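"""Vascular-bed size and percent-regression scoring.

The peripheral vascular bed of a colony is bounded outside by the ampullae
border and inside by the border of the zooid bodies.  Its size is scored as
S_vb = p_a − p_b, the difference of the two border perimeters (a length, as
the original protocol defines it — no area proxy is substituted), and drug-
induced regression as 100·(S_ctrl − S_regres)/S_ctrl percent, which may be
negative when the bed grew.  Outlines may be supplied as traced closed
polygons or as precomputed perimeter scalars; units of the two perimeters
must match and are carried as an explicit tag, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .stats import GroupComparison, compare_groups

__all__ = [
    "VascularBedOutline",
    "polygon_perimeter",
    "bed_size",
    "outline_from_polygons",
    "percent_regression",
    "compare_regression",
]


def polygon_perimeter(vertices) -> float:
    """Perimeter of a closed polygon given as an (N, 2) vertex list
    (the closing edge back to the first vertex is included)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 (x, y) vertices")
    if not np.all(np.isfinite(v)):
        raise ParameterError("polygon vertices must be finite")
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class VascularBedOutline:
    """Perimeters of the ampullae border (p_a) and body border (p_b).

    Equality (p_a == p_b, zero bed) is allowed so a fully regressed bed is
    representable; the :func:`bed_size` operation itself rejects p_a <= p_b
    because a measured bed must be positive.
    """

    p_a: float
    p_b: float
    units: str = "px"

    def __post_init__(self) -> None:
        if self.p_b < 0:
            raise GeometryError("p_b cannot be negative")
        if self.p_a < self.p_b:
            raise GeometryError("ampullae border cannot be shorter than body border")

    @property
    def s_vb(self) -> float:
        """Vascular-bed size S_vb = p_a − p_b (same units as the perimeters)."""
        return self.p_a - self.p_b


def bed_size(p_a: float, p_b: float, units_a: str = "px", units_b: str = "px") -> float:
    """S_vb = p_a − p_b.  Requires p_a > p_b >= 0 and matching units."""
    if units_a != units_b:
        raise ParameterError(f"perimeter units differ: {units_a!r} vs {units_b!r}")
    if p_a <= p_b:
        raise GeometryError("bed size would be non-positive (p_a must exceed p_b)")
    return VascularBedOutline(p_a=p_a, p_b=p_b, units=units_a).s_vb


def outline_from_polygons(ampullae_polygon, body_polygon, units: str = "px") -> VascularBedOutline:
    """Build an outline record from traced closed polygons."""
    return VascularBedOutline(
        p_a=polygon_perimeter(ampullae_polygon),
        p_b=polygon_perimeter(body_polygon),
        units=units,
    )


def percent_regression(s_ctrl: float, s_regres: float) -> float:
    """100·(S_ctrl − S_regres)/S_ctrl; negative when the bed grew."""
    if s_ctrl <= 0:
        raise ParameterError("control bed size must be positive")
    if s_regres < 0:
        raise ParameterError("post-treatment bed size cannot be negative")
    return 100.0 * (s_ctrl - s_regres) / s_ctrl


def compare_regression(young_percents, old_percents, paired: bool = True) -> GroupComparison:
    """Compare percent-regression values between age groups with a two-tailed
    t-test (paired by default, matching the matched-colony design)."""
    design = "paired" if paired else "two-sample"
    return compare_groups(
        young_percents,
        old_percents,
        names=("young", "old"),
        metric="percent_regression",
        design=design,
    )
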