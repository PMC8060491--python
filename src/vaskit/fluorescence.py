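"""Corrected total fluorescence (CTF) quantification.

CTF = integrated ROI intensity − (ROI area × mean background fluorescence),
the standard background-corrected total intensity of a region.  "ROI" in the
formula is the ROI *area* in pixels, the usual CTCF convention.  The
subtraction makes CTF exactly invariant to any constant offset added to the
whole image, while a multiplicative gain scales CTF linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MaskError, ParameterError

__all__ = ["RoiFluorescence", "compute_ctf", "normalize_to_controls"]


@dataclass(frozen=True)
class RoiFluorescence:
    integrated_intensity: float
    roi_area_px: int
    background_mean: float
    ctf: float

    def __post_init__(self) -> None:
        if self.roi_area_px <= 0:
            raise ParameterError("ROI area must be positive")


def _as_mask(m, shape, name: str) -> np.ndarray:
    mask = np.asarray(m, dtype=bool)
    if mask.shape != shape:
        raise MaskError(f"{name} shape {mask.shape} does not match image {shape}")
    if not mask.any():
        raise MaskError(f"{name} is empty")
    return mask


def compute_ctf(image: np.ndarray, roi_mask, background_mask) -> RoiFluorescence:
    """CTF of one ROI against a background-only ROI from the same image."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("expected a single-channel 2D image")
    roi = _as_mask(roi_mask, img.shape, "roi_mask")
    bg = _as_mask(background_mask, img.shape, "background_mask")
    if np.any(roi & bg):
        raise MaskError("ROI and background masks overlap")
    integrated = float(img[roi].sum())
    area = int(roi.sum())
    bg_mean = float(img[bg].mean())
    return RoiFluorescence(
        integrated_intensity=integrated,
        roi_area_px=area,
        background_mean=bg_mean,
        ctf=integrated - area * bg_mean,
    )


def normalize_to_controls(samples, controls) -> list[float]:
    """Divide each sample CTF by the mean control CTF (fold-change scale)."""
    ctf_of = lambda r: r.ctf if isinstance(r, RoiFluorescence) else float(r)
    ctrl = [ctf_of(c) for c in controls]
    if not ctrl:
        raise ParameterError("need at least one control")
    mean_ctrl = float(np.mean(ctrl))
    if mean_ctrl == 0:
        raise ParameterError("mean control CTF is zero; normalization undefined")
    return [ctf_of(s) / mean_ctrl for s in samples]
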