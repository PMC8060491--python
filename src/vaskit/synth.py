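"""Synthetic ground-truth generators for every analysis stage.

No imaging data ships with the toolkit, so each stage is validated by
parameter recovery on synthetic inputs:

* vessel movies — a straight horizontal vessel whose lumen carries advected
  high-contrast blood cells (dark Gaussian blobs on a bright tunic-like
  background), with a static axial intensity gradient, immobile speckles
  that produce the vertical kymograph stripes of real recordings, and
  additive Gaussian noise.  Particles wrap around the segment so streak
  density is stationary in time.  The default calibration matches the
  reference acquisition (0.313 µm/px, 0.177 s/frame).
* Murray networks — bifurcating trees whose child diameters satisfy
  d_parent^n = Σ d_child^n with flow conserved at every branch point, plus
  multiplicative lognormal measurement noise on the reported d and v.
* cell mosaics — non-overlapping rasterized ellipses with controlled mean
  area, area CV and elongation, plus a bright-boundary rendering and a
  ground-truth shape table.
* vascular-bed outlines — control/post-treatment polygon pairs whose bed
  sizes differ by exactly a requested fraction.

All randomness flows from the explicit ``seed`` of each parameter set; the
same parameters always produce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .errors import ParameterError, PlacementError
from .kymo import TimeLapseStack
from .hemodynamics import VesselRecord
from .regression import VascularBedOutline, percent_regression, polygon_perimeter

__all__ = [
    "FlowSimParams",
    "MurrayNetParams",
    "ShapeSimParams",
    "MurrayNetwork",
    "CellMosaic",
    "BedOutlinePair",
    "simulate_vessel_movie",
    "simulate_murray_network",
    "simulate_cell_mosaic",
    "sample_cell_population",
    "simulate_bed_outlines",
    "ellipse_circularity",
]


# --------------------------------------------------------------------------
# vessel movies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowSimParams:
    """Parameters of the advected-particle vessel movie.

    velocity_profile is the signed axial displacement in px/frame — a scalar
    for steady flow or a length n_frames-1 sequence for time-varying flow
    (e.g. the direction reversals seen in real recordings).
    particle_density is particles per 100 px of vessel length; 8 emulates the
    dense streaks of young colonies, 2 the sparse streaks of old ones.
    particle_contrast is signed; the default is negative (cells darker than
    the tunic background).  lumen_shading is the static optical absorption
    of the vessel band itself — the lumen is visibly darker than the tunic
    even between cell transits, so the minimal projection shows the vessel
    as a dark band with edges at the anatomical boundary, which is what the
    diameter measurement reads out.
    """

    n_frames: int = 256
    length_px: int = 300
    width_px: int = 40
    velocity_profile: float | tuple = 2.0
    particle_density: float = 8.0
    particle_radius_px: float = 2.0
    particle_contrast: float = -0.5
    lumen_shading: float = 0.6
    background_level: float = 1.0
    background_gradient: float = 0.0005
    n_immobile: int = 3
    noise_sigma: float = 0.02
    pixel_size_um: float = 0.313
    frame_interval_s: float = 0.177
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.length_px <= 0 or self.width_px <= 0 or self.particle_radius_px <= 0:
            raise ParameterError("lengths must be positive")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma cannot be negative")
        if self.lumen_shading < 0:
            raise ParameterError("lumen_shading cannot be negative")
        if self.particle_density < 0 or self.n_immobile < 0:
            raise ParameterError("counts cannot be negative")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("calibration values must be positive")

    def velocity_per_frame(self) -> np.ndarray:
        """Displacement (px) applied between consecutive frames, length n_frames-1."""
        v = np.asarray(self.velocity_profile, dtype=float)
        if v.ndim == 0:
            return np.full(self.n_frames - 1, float(v))
        if v.size == self.n_frames - 1:
            return v.astype(float)
        if v.size == self.n_frames:
            return v[:-1].astype(float)
        raise ParameterError(
            f"velocity_profile length {v.size} incompatible with n_frames={self.n_frames}"
        )


def _stamp_blobs(frame: np.ndarray, xs, ys, amplitude: float, sigma: float, wrap_len: int) -> None:
    """Add isotropic Gaussian blobs, wrapping across the axial (x) boundary."""
    h, w = frame.shape
    r = int(math.ceil(3 * sigma))
    yy = np.arange(-r, r + 1)
    for xc, yc in zip(np.atleast_1d(xs), np.atleast_1d(ys)):
        ix = int(round(xc))
        iy = int(round(yc))
        cols = np.arange(ix - r, ix + r + 1) % wrap_len
        rows = iy + yy
        ok = (rows >= 0) & (rows < h)
        dx = np.arange(ix - r, ix + r + 1) - xc  # axial distance before wrapping
        gy = np.exp(-(yy[ok] ** 2) / (2 * sigma**2))
        gx = np.exp(-(dx**2) / (2 * sigma**2))
        frame[np.ix_(rows[ok], cols)] += amplitude * np.outer(gy, gx)


def simulate_vessel_movie(params: FlowSimParams) -> TimeLapseStack:
    """Render a calibrated time-lapse of a straight vessel with advected cells.

    The vessel axis runs along x; the lumen spans ``width_px`` rows centered
    in a frame two blob-radii taller.  Particle x positions advance by the
    per-frame velocity and wrap at the segment ends (periodic axis), so the
    kymograph texture is stationary in time.  Immobile speckles stay fixed
    across frames; i.i.d. Gaussian noise is added last.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    margin = int(math.ceil(3 * p.particle_radius_px)) + 2
    height = p.width_px + 2 * margin
    cy = height / 2.0
    half_lumen = p.width_px / 2.0

    n_particles = int(round(p.particle_density * p.length_px / 100.0))
    x = rng.uniform(0, p.length_px, size=n_particles)
    y_pad = min(p.particle_radius_px, half_lumen)  # cells fit inside the lumen
    y_lo, y_hi = cy - half_lumen + y_pad, cy + half_lumen - y_pad
    y = rng.uniform(y_lo, y_hi, size=n_particles)

    imm_x = rng.uniform(0, p.length_px, size=p.n_immobile)
    imm_y = rng.uniform(cy - half_lumen, cy + half_lumen, size=p.n_immobile)

    velocity = p.velocity_per_frame()
    xg = np.arange(p.length_px, dtype=float)
    base = p.background_level + p.background_gradient * xg  # axial gradient
    # static optical absorption of the lumen: a dark band with an
    # antialiased 1-px edge exactly at the nominal vessel boundary
    yg = np.arange(height, dtype=float)
    inside = np.clip(half_lumen - np.abs(yg - cy) + 0.5, 0.0, 1.0)
    shading = p.lumen_shading * inside

    frames = np.empty((p.n_frames, height, p.length_px), dtype=float)
    for t in range(p.n_frames):
        frame = np.tile(base, (height, 1)) - shading[:, None]
        if p.n_immobile:
            _stamp_blobs(frame, imm_x, imm_y, p.particle_contrast, p.particle_radius_px, p.length_px)
        if n_particles:
            _stamp_blobs(frame, x, y, p.particle_contrast, p.particle_radius_px, p.length_px)
        frames[t] = frame
        if t < p.n_frames - 1 and n_particles:
            x = x + velocity[t]
            wrapped = (x < 0) | (x >= p.length_px)
            x = x % p.length_px
            # a wrapped particle is a fresh cell entering the segment:
            # re-draw its transverse position
            if wrapped.any():
                y = y.copy()
                y[wrapped] = rng.uniform(y_lo, y_hi, size=int(wrapped.sum()))
    if p.noise_sigma > 0:
        frames += rng.normal(0.0, p.noise_sigma, size=frames.shape)
    return TimeLapseStack(
        frames=frames, pixel_size_um=p.pixel_size_um, frame_interval_s=p.frame_interval_s
    )


# --------------------------------------------------------------------------
# Murray networks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MurrayNetParams:
    """A symmetric bifurcating tree obeying d_parent^n = Σ d_child^n with
    flow conservation; ``noise_sigma`` is the relative (lognormal)
    measurement noise applied to the reported diameter and velocity."""

    n_levels: int = 5
    exponent: float = 3.0
    root_diameter_um: float = 60.0
    root_flow_um3_s: float = 1.5e4
    children_per_branch: int = 2
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ParameterError("n_levels must be >= 2")
        if self.exponent <= 0:
            raise ParameterError("branching exponent must be positive")
        if self.root_diameter_um <= 0 or self.root_flow_um3_s <= 0:
            raise ParameterError("root diameter and flow must be positive")
        if self.children_per_branch < 2:
            raise ParameterError("children_per_branch must be >= 2")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma cannot be negative")


@dataclass(frozen=True)
class MurrayNetwork:
    """Generated network: measured records, true (noise-free) records and
    parent→child edges as index pairs into the record lists."""

    records: list
    true_records: list
    edges: list
    params: MurrayNetParams


def _speed_from_flow(q: float, d: float) -> float:
    return q / (math.pi * d**2 / 4.0)


def simulate_murray_network(params: MurrayNetParams) -> MurrayNetwork:
    """Generate one VesselRecord per tree segment.

    At each branch point the child diameter is d·c^(−1/n) (all children
    equal, so d_parent^n = Σ d_child^n holds exactly) and each child carries
    Q/c, conserving flow.  Velocity is Q over the cross-sectional area.
    Reported d and v are perturbed by exp(σ·N(0,1)); the reported Q is
    recomputed from the perturbed values so every record stays internally
    consistent with the plug-flow model.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    c = p.children_per_branch
    shrink = c ** (-1.0 / p.exponent)
    records, true_records, edges = [], [], []
    # level-order construction; all segments at a level are identical pre-noise
    index_of_level_start = []
    idx = 0
    for level in range(p.n_levels):
        index_of_level_start.append(idx)
        d = p.root_diameter_um * shrink**level
        q = p.root_flow_um3_s / c**level
        v = _speed_from_flow(q, d)
        for k in range(c**level):
            vid = f"L{level}S{k}"
            true_records.append(
                VesselRecord(vessel_id=vid, diameter_um=d, v_max_um_s=v, q_flow_um3_s=q, age_group="truth")
            )
            if p.noise_sigma > 0:
                d_meas = d * math.exp(p.noise_sigma * rng.standard_normal())
                v_meas = v * math.exp(p.noise_sigma * rng.standard_normal())
            else:
                d_meas, v_meas = d, v
            q_meas = v_meas * math.pi * d_meas**2 / 4.0
            records.append(
                VesselRecord(
                    vessel_id=vid, diameter_um=d_meas, v_max_um_s=v_meas, q_flow_um3_s=q_meas, age_group="synthetic"
                )
            )
            idx += 1
    for level in range(p.n_levels - 1):
        start, nxt = index_of_level_start[level], index_of_level_start[level + 1]
        for k in range(c**level):
            parent = start + k
            for j in range(c):
                edges.append((parent, nxt + k * c + j))
    return MurrayNetwork(records=records, true_records=true_records, edges=edges, params=p)


# --------------------------------------------------------------------------
# cell mosaics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSimParams:
    """Elliptical cell mosaic with controlled area distribution and elongation.

    Areas are gamma-distributed with the requested mean (µm²) and coefficient
    of variation; elongation is the major/minor axis ratio (1 = disks).
    """

    n_cells: int = 50
    mean_area_um2: float = 30.9
    area_cv: float = 0.25
    elongation: float = 1.0
    image_size_px: int = 512
    pixel_size_um: float = 0.25
    seed: int = 0
    max_retries_per_cell: int = 500

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.mean_area_um2 <= 0 or self.pixel_size_um <= 0 or self.image_size_px <= 0:
            raise ParameterError("sizes must be positive")
        if self.area_cv < 0:
            raise ParameterError("area_cv cannot be negative")
        if self.elongation < 1:
            raise ParameterError("elongation (major/minor ratio) must be >= 1")


@dataclass(frozen=True)
class CellMosaic:
    """Rasterized mosaic: ground-truth labels, a bright-boundary rendering,
    and the intended per-cell shape table."""

    labels: np.ndarray
    boundary_image: np.ndarray
    truth: pd.DataFrame
    pixel_size_um: float


def ellipse_circularity(elongation: float) -> float:
    """Exact circularity 4πA/P² of an ellipse with the given axis ratio,
    using the complete elliptic integral for the perimeter."""
    if elongation < 1:
        raise ParameterError("elongation must be >= 1")
    a, b = elongation, 1.0
    m = 1.0 - (b / a) ** 2
    perimeter = 4.0 * a * ellipe(m)
    area = math.pi * a * b
    return 4.0 * math.pi * area / perimeter**2


def sample_cell_population(params: ShapeSimParams) -> pd.DataFrame:
    """Ground-truth shape table (area, perimeter, circularity) without
    rasterization — the intended values the mosaic encodes."""
    p = params
    rng = np.random.default_rng(p.seed)
    if p.area_cv == 0:
        areas = np.full(p.n_cells, p.mean_area_um2)
    else:
        shape_k = 1.0 / p.area_cv**2
        areas = rng.gamma(shape_k, p.mean_area_um2 / shape_k, size=p.n_cells)
    circ = ellipse_circularity(p.elongation)
    a_semi = np.sqrt(areas * p.elongation / math.pi)  # semi-major axis (µm)
    b_semi = a_semi / p.elongation
    m = 1.0 - (b_semi / a_semi) ** 2
    perim = 4.0 * a_semi * ellipe(m)
    return pd.DataFrame(
        {
            "label": np.arange(1, p.n_cells + 1),
            "area_um2": areas,
            "perimeter_um": perim,
            "circularity": np.full(p.n_cells, circ),
            "orientation_rad": rng.uniform(0, math.pi, size=p.n_cells),
        }
    )


def simulate_cell_mosaic(params: ShapeSimParams) -> CellMosaic:
    """Place non-overlapping ellipses and rasterize label + boundary images.

    Placement is rejection sampling on bounding circles with a 3-px gap;
    exceeding the retry budget raises :class:`PlacementError`.  The boundary
    image renders a bright ~2 px ridge on each cell outline over a dark
    background, emulating membrane staining.
    """
    p = params
    truth = sample_cell_population(p)
    rng = np.random.default_rng(p.seed + 1)  # placement stream, separate from shape stream
    size = p.image_size_px
    a_px = np.sqrt(truth["area_um2"].to_numpy() * p.elongation / math.pi) / p.pixel_size_um
    b_px = a_px / p.elongation
    theta = truth["orientation_rad"].to_numpy()
    gap = 3.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for i in range(p.n_cells):
        r = a_px[i]
        lo, hi = r + 2.0, size - r - 2.0
        if hi <= lo:
            raise PlacementError(f"cell {i + 1} larger than the image")
        placed = False
        for _ in range(p.max_retries_per_cell):
            cx, cy = rng.uniform(lo, hi, size=2)
            if all((cx - x) ** 2 + (cy - y) ** 2 > (r + rr + gap) ** 2 for (x, y), rr in zip(centers, radii)):
                centers.append((cx, cy))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise PlacementError(f"could not place cell {i + 1} without overlap")

    labels = np.zeros((size, size), dtype=np.int32)
    yy, xx = np.mgrid[0:size, 0:size]
    for i, (cx, cy) in enumerate(centers):
        ct, st = math.cos(theta[i]), math.sin(theta[i])
        u = (xx - cx) * ct + (yy - cy) * st
        w = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a_px[i]) ** 2 + (w / b_px[i]) ** 2 <= 1.0
        labels[inside] = i + 1

    from scipy.ndimage import binary_dilation, binary_erosion

    fg = labels > 0
    ridge = binary_dilation(fg, iterations=1) & ~binary_erosion(fg, iterations=1)
    boundary = np.full((size, size), 0.05)
    boundary[ridge] = 1.0
    boundary += rng.normal(0.0, 0.01, size=boundary.shape)
    return CellMosaic(labels=labels, boundary_image=boundary, truth=truth, pixel_size_um=p.pixel_size_um)


# --------------------------------------------------------------------------
# vascular-bed outlines
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BedOutlinePair:
    """Control and post-treatment outlines with their traced polygons."""

    control: VascularBedOutline
    treated: VascularBedOutline
    control_polygons: dict
    treated_polygons: dict

    @property
    def percent_regression(self) -> float:
        return percent_regression(self.control.s_vb, self.treated.s_vb)


def _jittered_ring(rng: np.random.Generator, radius: float, n_vertices: int = 64, jitter: float = 0.03) -> np.ndarray:
    ang = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    r = radius * (1.0 + jitter * rng.uniform(-1, 1, size=n_vertices))
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def simulate_bed_outlines(
    area_loss_fraction: float,
    seed: int = 0,
    body_radius: float = 100.0,
    bed_width_factor: float = 0.6,
) -> BedOutlinePair:
    """Control/post-treatment outline pair losing exactly the given fraction
    of vascular-bed size.

    The body border is a jittered ring; the control ampullae border is the
    same shape scaled outward.  The treated ampullae border is rescaled about
    the origin so that S_treated = (1 − fraction)·S_control exactly (polygon
    perimeters scale linearly with the scale factor).
    """
    if not (0.0 <= area_loss_fraction <= 1.0):
        raise ParameterError("loss fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    body = _jittered_ring(rng, body_radius)
    p_b = polygon_perimeter(body)
    k_ctrl = 1.0 + bed_width_factor
    amp_ctrl = body * k_ctrl
    p_a_ctrl = polygon_perimeter(amp_ctrl)
    s_ctrl = p_a_ctrl - p_b
    s_treat = (1.0 - area_loss_fraction) * s_ctrl
    k_treat = (p_b + s_treat) / p_b  # target ampullae perimeter / body perimeter
    amp_treat = body * k_treat
    control = VascularBedOutline(p_a=p_a_ctrl, p_b=p_b, units="px")
    treated = VascularBedOutline(p_a=polygon_perimeter(amp_treat), p_b=p_b, units="px")
    return BedOutlinePair(
        control=control,
        treated=treated,
        control_polygons={"ampullae": amp_ctrl, "body": body},
        treated_polygons={"ampullae": amp_treat, "body": body},
    )
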