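"""Flow velocimetry by lag-scanning correlation on normalized kymographs.

For each timepoint a local section of the kymograph (default 3 frames) is
examined: for every candidate signed shift s the Pearson correlation between
row pairs one frame apart, displaced by s, is averaged over the section.
The shift maximizing this correlation is the per-frame displacement, and
v = Δx/Δt converts to µm/s with the kymograph's calibration.  Timepoints
whose peak correlation does not exceed the gate (default 0.8) carry no
meaningful streak signal — few or no high-contrast particles — and are
flagged invalid rather than reported.

The correlation is evaluated on a central column window so every lag is
compared over the same number of columns.  Integer-lag argmax breaks ties
toward the smaller |s| (bias toward no flow under ambiguity); an optional
three-point parabolic refinement reduces quantization at low speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, NoValidTimepointsError, ParameterError, StateError
from .kymo import Kymograph

__all__ = [
    "VelocimetryConfig",
    "VelocityTrace",
    "VesselVelocitySummary",
    "estimate_velocity_trace",
    "summarize_vessel_velocity",
]


@dataclass(frozen=True)
class VelocimetryConfig:
    """Tunables of the correlation velocimeter.

    section_frames: rows per local section (>= 2); 3 matches the reference
    workflow.  corr_threshold: validity gate on the peak correlation, in
    (0, 1).  max_shift_px: half-range of the signed lag search.  subpixel:
    enable parabolic peak interpolation.
    """

    section_frames: int = 3
    corr_threshold: float = 0.8
    max_shift_px: int = 15
    subpixel: bool = True

    def __post_init__(self) -> None:
        if self.section_frames < 2:
            raise ParameterError("section_frames must be >= 2")
        if not (0.0 < self.corr_threshold < 1.0):
            raise ParameterError("corr_threshold must be in (0, 1)")
        if self.max_shift_px < 1:
            raise ParameterError("max_shift_px must be >= 1")


@dataclass(frozen=True)
class VelocityTrace:
    """Per-timepoint velocimetry output (arrays share one length)."""

    shift_px: np.ndarray  # signed displacement per frame; NaN where invalid
    velocity_um_s: np.ndarray  # signed velocity; NaN where invalid
    peak_corr: np.ndarray
    valid: np.ndarray  # boolean gate: peak_corr > threshold
    pixel_size_um: float
    frame_interval_s: float
    config: VelocimetryConfig = field(default_factory=VelocimetryConfig)

    @property
    def n_timepoints(self) -> int:
        return self.shift_px.size

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(self.n_timepoints),
                "shift_px": self.shift_px,
                "velocity_um_s": self.velocity_um_s,
                "peak_corr": self.peak_corr,
                "valid": self.valid,
            }
        )


def _pairwise_lag_correlations(values: np.ndarray, max_shift: int) -> np.ndarray:
    """Pearson correlation between consecutive-row pairs at every signed lag.

    Returns an array (n_pairs, 2*max_shift+1); column j corresponds to lag
    s = j - max_shift.  Row t of the earlier frame is compared, over a fixed
    central column window, with row t+1 displaced by s; positive s means the
    pattern moved toward larger axial position.
    """
    t, w = values.shape
    m = max_shift
    wc = w - 2 * m
    if wc < 2:
        raise GeometryError("kymograph narrower than twice the shift search range")
    a = values[:-1, m : w - m]
    a0 = a - a.mean(axis=1, keepdims=True)
    sa = np.sqrt((a0**2).sum(axis=1))
    lags = np.arange(-m, m + 1)
    out = np.empty((t - 1, lags.size), dtype=float)
    b_all = values[1:]
    for j, s in enumerate(lags):
        b = b_all[:, m + s : w - m + s]
        b0 = b - b.mean(axis=1, keepdims=True)
        sb = np.sqrt((b0**2).sum(axis=1))
        denom = sa * sb
        num = (a0 * b0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(denom > 0, num / denom, 0.0)
        out[:, j] = c
    return out


def estimate_velocity_trace(kymo: Kymograph, config: VelocimetryConfig | None = None) -> VelocityTrace:
    """Estimate the signed per-timepoint flow velocity of a normalized kymograph.

    Timepoint t summarizes rows [t, t + section_frames); there are
    ``n_rows - section_frames + 1`` timepoints.  Invalid timepoints (peak
    correlation at or below the gate) carry NaN shift and velocity.
    """
    cfg = config or VelocimetryConfig()
    if not kymo.normalized:
        raise StateError("velocimetry requires a normalized kymograph")
    if kymo.n_timepoints < cfg.section_frames:
        raise GeometryError("kymograph shorter than one section")
    corr = _pairwise_lag_correlations(kymo.values, cfg.max_shift_px)
    n_pairs_per_section = cfg.section_frames - 1
    n_t = kymo.n_timepoints - cfg.section_frames + 1
    # average pair correlations within each section via cumulative sums
    c = np.cumsum(corr, axis=0)
    c = np.vstack([np.zeros((1, corr.shape[1])), c])
    section = (c[n_pairs_per_section:] - c[:-n_pairs_per_section])[:n_t] / n_pairs_per_section

    m = cfg.max_shift_px
    lags = np.arange(-m, m + 1)
    # argmax with ties resolved toward the smaller |s|: scan lags in order of
    # increasing |s| and keep the first maximum.
    order = np.argsort(np.abs(lags), kind="stable")
    best_idx_in_order = np.argmax(section[:, order], axis=1)
    peak_idx = order[best_idx_in_order]  # index into natural lag ordering
    peak_corr = section[np.arange(n_t), peak_idx]
    shift = lags[peak_idx].astype(float)

    if cfg.subpixel:
        interior = (peak_idx > 0) & (peak_idx < lags.size - 1)
        i = np.where(interior)[0]
        c0 = section[i, peak_idx[i]]
        cm = section[i, peak_idx[i] - 1]
        cp = section[i, peak_idx[i] + 1]
        denom = cm - 2.0 * c0 + cp
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(denom < 0, 0.5 * (cm - cp) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        shift[i] = shift[i] + delta

    valid = peak_corr > cfg.corr_threshold
    velocity = shift * kymo.pixel_size_um / kymo.frame_interval_s
    shift = np.where(valid, shift, np.nan)
    velocity = np.where(valid, velocity, np.nan)
    return VelocityTrace(
        shift_px=shift,
        velocity_um_s=velocity,
        peak_corr=peak_corr,
        valid=valid,
        pixel_size_um=kymo.pixel_size_um,
        frame_interval_s=kymo.frame_interval_s,
        config=cfg,
    )


@dataclass(frozen=True)
class VesselVelocitySummary:
    """Per-vessel aggregation over the valid timepoints of a trace."""

    v_max_um_s: float  # max over valid timepoints of |velocity|
    v_median_um_s: float  # median of |velocity| over valid timepoints
    valid_fraction: float
    n_reversals: int  # sign flips between consecutive valid timepoints
    n_timepoints: int


def summarize_vessel_velocity(trace: VelocityTrace) -> VesselVelocitySummary:
    """Summarize a velocity trace: maximum flow speed, median speed, the
    fraction of valid timepoints and the number of flow-direction reversals.

    Raises :class:`NoValidTimepointsError` when no timepoint passes the
    correlation gate (the vessel is excluded, as low-contrast recordings are).
    """
    v = trace.velocity_um_s[trace.valid]
    if v.size == 0:
        raise NoValidTimepointsError("no valid timepoints in velocity trace")
    speed = np.abs(v)
    signs = np.sign(v)
    signs = signs[signs != 0]
    reversals = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0
    return VesselVelocitySummary(
        v_max_um_s=float(speed.max()),
        v_median_um_s=float(np.median(speed)),
        valid_fraction=trace.valid_fraction,
        n_reversals=reversals,
        n_timepoints=trace.n_timepoints,
    )
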