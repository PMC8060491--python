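"""File I/O: multi-page TIFF stacks with JSON calibration sidecars, ROI
JSON, kymograph TIFF/CSV, velocity-trace and vessel-record CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .hemodynamics import VesselRecord
from .kymo import Kymograph, LineRoi, TimeLapseStack
from .velocimetry import VelocityTrace

__all__ = [
    "save_stack",
    "load_stack",
    "save_roi",
    "load_roi",
    "save_kymograph",
    "load_kymograph",
    "trace_to_csv",
    "records_to_csv",
    "records_from_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(stack: TimeLapseStack, path) -> Path:
    """Write a multi-page TIFF plus a ``<name>.tif.json`` calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {"pixel_size_um": stack.pixel_size_um, "frame_interval_s": stack.frame_interval_s},
            indent=2,
        )
    )
    return path


def load_stack(path) -> TimeLapseStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return TimeLapseStack(
        frames=tifffile.imread(path),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
    )


def save_roi(roi: LineRoi, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {"points": roi.points.tolist(), "thickness_um": roi.thickness_um, "kind": roi.kind},
            indent=2,
        )
    )
    return path


def load_roi(path) -> LineRoi:
    data = json.loads(Path(path).read_text())
    return LineRoi(
        points=np.asarray(data["points"], dtype=float),
        thickness_um=float(data.get("thickness_um", 3.0)),
        kind=data.get("kind", "axial"),
    )


def save_kymograph(kymo: Kymograph, path) -> Path:
    """TIFF for ``.tif``/``.tiff`` paths, CSV otherwise; calibration goes to
    a JSON sidecar in both cases."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, kymo.values.astype(np.float32))
    else:
        np.savetxt(path, kymo.values, delimiter=",")
    _sidecar(path).write_text(
        json.dumps(
            {
                "pixel_size_um": kymo.pixel_size_um,
                "frame_interval_s": kymo.frame_interval_s,
                "normalized": kymo.normalized,
            },
            indent=2,
        )
    )
    return path


def load_kymograph(path) -> Kymograph:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
    else:
        values = np.loadtxt(path, delimiter=",")
    return Kymograph(
        values=np.asarray(values, dtype=float),
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        normalized=bool(meta.get("normalized", False)),
    )


def _write_csv_with_header(df: pd.DataFrame, path: Path, header_lines: list[str]) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    return path


def trace_to_csv(trace: VelocityTrace, path, header_lines: list[str] | None = None) -> Path:
    return _write_csv_with_header(trace.to_dataframe(), Path(path), header_lines or [])


def records_to_csv(records, path, header_lines: list[str] | None = None) -> Path:
    df = pd.DataFrame(
        {
            "vessel_id": [r.vessel_id for r in records],
            "age_group": [r.age_group for r in records],
            "diameter_um": [r.diameter_um for r in records],
            "v_max_um_s": [r.v_max_um_s for r in records],
            "q_flow_um3_s": [r.q_flow_um3_s for r in records],
        }
    )
    return _write_csv_with_header(df, Path(path), header_lines or [])


def records_from_csv(path) -> list[VesselRecord]:
    df = pd.read_csv(path, comment="#")
    required = {"vessel_id", "diameter_um", "v_max_um_s", "q_flow_um3_s"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"vessel table missing columns: {sorted(missing)}")
    return [
        VesselRecord(
            vessel_id=str(row.vessel_id),
            diameter_um=float(row.diameter_um),
            v_max_um_s=float(row.v_max_um_s),
            q_flow_um3_s=float(row.q_flow_um3_s),
            age_group=str(getattr(row, "age_group", "")),
        )
        for row in df.itertuples(index=False)
    ]
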