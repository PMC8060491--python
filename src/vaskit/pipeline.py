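"""End-to-end flow pipeline: stack → kymograph → velocimetry → diameter →
volumetric flow → branching-exponent fit.

Vessels are processed independently with per-vessel failure isolation: a
vessel whose recording yields no valid velocity timepoint, or whose diameter
profile cannot be measured, is skipped with a logged reason — mirroring the
exclusion of low-contrast vessels in manual workflows — and the fit proceeds
on the remainder.  Every output file carries the configuration hash so runs
are auditable; reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .errors import FitError, ParameterError, VaskitError
from .hemodynamics import (
    BranchingFit,
    VesselRecord,
    fit_branching_exponent,
    measure_diameter,
    volumetric_flow,
)
from .kymo import (
    DEFAULT_BACKGROUND_WINDOW,
    LineRoi,
    TimeLapseStack,
    extract_kymograph,
    normalize_kymograph,
)
from .velocimetry import VelocimetryConfig, estimate_velocity_trace, summarize_vessel_velocity

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "VesselInput", "analyze_vessel", "run_flow_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the flow pipeline in one serializable record."""

    velocimetry: VelocimetryConfig = field(default_factory=VelocimetryConfig)
    background_window_frames: int = DEFAULT_BACKGROUND_WINDOW
    diameter_method: str = "fwhm"
    profile_model: str = "plug"
    variance_assumption: str = "pooled"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass(frozen=True)
class VesselInput:
    """One vessel's inputs, in memory or as paths loaded lazily."""

    vessel_id: str
    stack: TimeLapseStack | None = None
    axial_roi: LineRoi | None = None
    cross_roi: LineRoi | None = None
    stack_path: str | None = None
    axial_roi_path: str | None = None
    cross_roi_path: str | None = None
    age_group: str = ""

    def load(self) -> tuple[TimeLapseStack, LineRoi, LineRoi]:
        stack = self.stack if self.stack is not None else vio.load_stack(self.stack_path)
        axial = self.axial_roi if self.axial_roi is not None else vio.load_roi(self.axial_roi_path)
        cross = self.cross_roi if self.cross_roi is not None else vio.load_roi(self.cross_roi_path)
        return stack, axial, cross


def analyze_vessel(vessel: VesselInput, config: PipelineConfig) -> tuple[VesselRecord, dict]:
    """Run the full measurement chain on one vessel.

    Returns the VesselRecord plus a dict of intermediates (kymographs, the
    velocity trace and its summary) for inspection or saving.
    """
    stack, axial_roi, cross_roi = vessel.load()
    raw = extract_kymograph(stack, axial_roi)
    norm = normalize_kymograph(raw, window_frames=config.background_window_frames)
    trace = estimate_velocity_trace(norm, config.velocimetry)
    summary = summarize_vessel_velocity(trace)
    diameter = measure_diameter(
        stack.min_projection(), cross_roi, stack.pixel_size_um, method=config.diameter_method
    )
    q = volumetric_flow(summary.v_max_um_s, diameter, profile_model=config.profile_model)
    record = VesselRecord(
        vessel_id=vessel.vessel_id,
        diameter_um=diameter,
        v_max_um_s=summary.v_max_um_s,
        q_flow_um3_s=q,
        age_group=vessel.age_group,
    )
    return record, {"raw_kymograph": raw, "normalized_kymograph": norm, "trace": trace, "summary": summary}


def run_flow_pipeline(
    vessels,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> tuple[list[VesselRecord], BranchingFit, list[tuple[str, str]]]:
    """Measure every vessel, fit the branching exponent, optionally write outputs.

    Returns (records, fit, failures) where ``failures`` lists
    (vessel_id, reason) for vessels skipped by per-vessel isolation.  Raises
    :class:`ParameterError` on an empty vessel list and :class:`FitError`
    when fewer than 3 vessels survive.
    """
    vessels = list(vessels)
    if not vessels:
        raise ParameterError("no vessels given")
    cfg = config or PipelineConfig()
    records: list[VesselRecord] = []
    failures: list[tuple[str, str]] = []
    intermediates: dict[str, dict] = {}
    for vessel in vessels:
        try:
            record, inter = analyze_vessel(vessel, cfg)
        except VaskitError as exc:
            logger.warning("vessel %s skipped: %s", vessel.vessel_id, exc)
            failures.append((vessel.vessel_id, str(exc)))
            continue
        records.append(record)
        intermediates[vessel.vessel_id] = inter
    if len(records) < 3:
        raise FitError(f"only {len(records)} vessels measured; need >= 3 for the fit")
    fit = fit_branching_exponent(records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = [f"config_hash: {cfg.config_hash()}", f"config: {json.dumps(cfg.to_dict(), sort_keys=True)}"]
        vio.records_to_csv(records, out / "vessel_records.csv", header_lines=header)
        for vid, inter in intermediates.items():
            vio.save_kymograph(inter["normalized_kymograph"], out / f"kymograph_{vid}.csv")
            vio.trace_to_csv(inter["trace"], out / f"trace_{vid}.csv", header_lines=header)
        report = {
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "exponent": fit.exponent,
            "intercept": fit.intercept,
            "exponent_stderr": fit.exponent_stderr,
            "r_squared": fit.r_squared,
            "n_vessels": fit.n_vessels,
            "failures": failures,
        }
        (out / "branching_fit.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return records, fit, failures


def render_network_vessels(
    network,
    flow_template=None,
    seed: int = 0,
    max_vessels: int | None = None,
) -> list[VesselInput]:
    """Render the segments of a synthetic Murray network into vessel movies.

    Each segment's true diameter and velocity (converted to px and px/frame
    with the template calibration) parameterize one movie; the center-line
    and cross ROIs are placed on the known geometry.  This closes the loop
    for full-chain recovery: network → movies → pipeline → exponent.
    """
    from dataclasses import replace

    from .synth import FlowSimParams, simulate_vessel_movie

    template = flow_template or FlowSimParams()
    rng = np.random.default_rng(seed)
    truth = network.true_records
    if max_vessels is not None and len(truth) > max_vessels:
        # spread selection across levels for diameter coverage
        idx = np.linspace(0, len(truth) - 1, max_vessels).round().astype(int)
        truth = [truth[i] for i in idx]
    inputs: list[VesselInput] = []
    for rec in truth:
        d_px = rec.diameter_um / template.pixel_size_um
        v_px = rec.v_max_um_s * template.frame_interval_s / template.pixel_size_um
        params = replace(
            template,
            width_px=int(round(d_px)),
            velocity_profile=float(v_px),
            # cell count scales with the cross-section so wider vessels keep
            # the same volume fraction of circulating cells
            particle_density=template.particle_density * max(d_px, 1.0) / 40.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        stack = simulate_vessel_movie(params)
        _, height, length = stack.shape
        cy = height / 2.0
        axial = LineRoi(points=[(2.0, cy), (length - 3.0, cy)], kind="axial")
        cross = LineRoi(points=[(length / 2.0, 1.0), (length / 2.0, height - 2.0)], kind="cross")
        inputs.append(
            VesselInput(vessel_id=rec.vessel_id, stack=stack, axial_roi=axial, cross_roi=cross, age_group="synthetic")
        )
    return inputs
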