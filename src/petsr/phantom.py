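"""Synthetic beating-heart phantom with analytic ground truth.

A left-ventricle-like annulus (wall activity 4, cavity and background
1, in SUV-like units) contracts radially and cyclically over the
cardiac cycle; every frame and its displacement field relative to the
reference (end-diastole) phase are known in closed form.  The module
also produces a speckled anatomical (B-mode-like) rendering of the
same motion, and degrades the activity frames into gated low-count
PET frames through the warp -> decimate -> blur -> count-noise chain,
so the registration and super-resolution stages can be validated
end-to-end against exact truth.

Frame *k* of *n* is the reference annulus scaled radially by

    s_k = 1 - A (1 - cos(2 pi k / n)) / 2,

about the grid centre (plus an optional rigid craniocaudal
translation), where ``A`` is the contraction amplitude as a fraction
of radius.  The pull-back field mapping reference coordinates into
frame *k* is then exactly ``M_k(x) = (s_k - 1) x + t_k`` in centred
pixel coordinates, consistent with the convention the registration and
SR stages use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import GatedSequence, Image2D, MotionField, PSFModel
from .srcore import downsample, gaussian_blur, invert_mvf, warp_image

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "make_beating_phantom",
    "make_anatomical_sequence",
    "degrade_sequence",
]


@dataclass
class PhantomConfig:
    """Geometry, activity and motion of the synthetic phantom.

    Radii are in mm at the reference phase.  Defaults give a
    rodent-scale ventricle: 12.8 mm field of view at 0.1 mm/px, a
    1.5 mm thick wall, 16 frames and a 5 % radial contraction.
    """

    grid_size: int = 128
    spacing_hr: float = 0.1
    n_frames: int = 16
    wall_value: float = 4.0
    background_value: float = 1.0
    cavity_value: float = 1.0
    inner_radius: float = 2.0
    outer_radius: float = 3.5
    contraction_amplitude: float = 0.05
    translation_amplitude_mm: float = 0.0
    defect_arc_deg: Optional[float] = None
    defect_center_deg: float = 90.0
    defect_value: float = 1.7
    edge_width_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inner_radius < self.outer_radius:
            raise ValueError("inner_radius must be smaller than outer_radius")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.contraction_amplitude < 0 or self.translation_amplitude_mm < 0:
            raise ValueError("motion amplitudes must be non-negative")
        half_fov = self.grid_size * self.spacing_hr / 2.0
        if self.outer_radius + 2 * self.edge_width_px * self.spacing_hr >= half_fov:
            raise ValueError("outer_radius exceeds the field of view")
        if self.contraction_amplitude >= 1.0:
            raise ValueError("contraction would collapse the inner radius")


@dataclass
class PhantomTruth:
    """Ground-truth bundle: frames, analytic motion fields and ROI masks."""

    hr_frames: GatedSequence
    true_mvfs: list[MotionField]
    wall_roi: np.ndarray
    cavity_roi: np.ndarray
    defect_roi: Optional[np.ndarray]
    config: PhantomConfig

    @property
    def reference(self) -> Image2D:
        return self.hr_frames[0]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0 for t<=0, 1 for t>=1, C2-smooth in between."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _edge(r: np.ndarray, r0: float, half_width: float) -> np.ndarray:
    """Smooth 1 -> 0 transition of the radial profile across radius ``r0``."""
    return 1.0 - _smoothstep((r - (r0 - half_width)) / (2.0 * half_width))


def _scales(cfg: PhantomConfig) -> np.ndarray:
    phases = 2.0 * np.pi * np.arange(cfg.n_frames) / cfg.n_frames
    return 1.0 - cfg.contraction_amplitude * (1.0 - np.cos(phases)) / 2.0


def _translations_px(cfg: PhantomConfig) -> np.ndarray:
    phases = 2.0 * np.pi * np.arange(cfg.n_frames) / cfg.n_frames
    return (cfg.translation_amplitude_mm / cfg.spacing_hr) * np.sin(phases)


def _centered_coords(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    c = (cfg.grid_size - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(cfg.grid_size), np.arange(cfg.grid_size), indexing="ij")
    return yy - c, xx - c


def _paint_annulus(cfg: PhantomConfig, scale: float, ty_px: float) -> np.ndarray:
    """Analytic activity map for one frame (radii scaled, optionally shifted)."""
    yc, xc = _centered_coords(cfg)
    yc = yc - ty_px
    r_mm = np.hypot(yc, xc) * cfg.spacing_hr
    # scale the transition width with the radii so every frame is exactly
    # the reference profile evaluated at r/scale (warp-consistent truth)
    w = cfg.edge_width_px * cfg.spacing_hr * scale
    r_in = cfg.inner_radius * scale
    r_out = cfg.outer_radius * scale
    inner = _edge(r_mm, r_in, w)   # 1 inside the cavity edge
    outer = _edge(r_mm, r_out, w)  # 1 inside the outer edge
    in_wall = outer - inner

    wall = np.full_like(r_mm, cfg.wall_value)
    if cfg.defect_arc_deg is not None:
        ang = np.degrees(np.arctan2(yc, xc))
        half = cfg.defect_arc_deg / 2.0
        d = np.abs((ang - cfg.defect_center_deg + 180.0) % 360.0 - 180.0)
        ang_w = np.degrees(2.0 * w / (cfg.outer_radius * scale))
        sector = _edge(d, half, ang_w)  # 1 inside the defect sector
        wall = wall + (cfg.defect_value - cfg.wall_value) * sector

    img = (
        cfg.background_value * (1.0 - outer)
        + cfg.cavity_value * inner
        + wall * in_wall
    )
    return img


def _rois(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    yc, xc = _centered_coords(cfg)
    r_mm = np.hypot(yc, xc) * cfg.spacing_hr
    # stay clear of the smooth edge transitions but keep a non-empty band
    # on coarse grids; the transition half-width is edge_width_px pixels
    margin = min(
        2.5 * cfg.edge_width_px * cfg.spacing_hr,
        (cfg.outer_radius - cfg.inner_radius) / 3.0,
    )
    in_band = (r_mm >= cfg.inner_radius + margin) & (r_mm <= cfg.outer_radius - margin)
    cavity = r_mm <= cfg.inner_radius - margin

    defect = None
    wall = in_band
    if cfg.defect_arc_deg is not None:
        ang = np.degrees(np.arctan2(yc, xc))
        d = np.abs((ang - cfg.defect_center_deg + 180.0) % 360.0 - 180.0)
        ang_margin = np.degrees(2.0 * margin / cfg.outer_radius)
        defect = in_band & (d <= cfg.defect_arc_deg / 2.0 - ang_margin)
        wall = in_band & (d >= cfg.defect_arc_deg / 2.0 + ang_margin)
    return wall, cavity, defect


def make_beating_phantom(cfg: PhantomConfig) -> PhantomTruth:
    """Build the gated high-resolution activity frames and their exact fields."""
    scales = _scales(cfg)
    trans = _translations_px(cfg)
    min_inner = cfg.inner_radius * scales.min()
    if min_inner <= 0:
        raise ValueError("contraction collapses the inner radius")

    yc, xc = _centered_coords(cfg)
    frames = []
    mvfs = []
    for k, (s, t) in enumerate(zip(scales, trans)):
        frames.append(Image2D(_paint_annulus(cfg, s, t), cfg.spacing_hr))
        if k == 0:
            mvfs.append(MotionField.zero((cfg.grid_size, cfg.grid_size), cfg.spacing_hr, 0))
        else:
            u = (s - 1.0) * xc
            v = (s - 1.0) * yc + t
            mvfs.append(MotionField(u, v, cfg.spacing_hr, k))

    wall, cavity, defect = _rois(cfg)
    return PhantomTruth(
        hr_frames=GatedSequence(frames),
        true_mvfs=mvfs,
        wall_roi=wall,
        cavity_roi=cavity,
        defect_roi=defect,
        config=cfg,
    )


def make_anatomical_sequence(
    truth: PhantomTruth, speckle_contrast: float = 0.3, seed: int = 0
) -> GatedSequence:
    """Speckled B-mode-like rendering of the phantom motion.

    Brightness is a monotone remap (square root) of activity,
    multiplied by a tissue-attached, spatially correlated multiplicative
    speckle texture that moves with the phantom, so the anatomical
    frames carry the same motion the PET frames do.  The speckle's
    coefficient of variation in a homogeneous region equals
    ``speckle_contrast``.
    """
    if speckle_contrast < 0:
        raise ValueError("speckle_contrast must be non-negative")
    cfg = truth.config
    rng = np.random.default_rng(seed)

    # correlated multiplicative texture in material (reference) coordinates
    noise = rng.standard_normal((cfg.grid_size, cfg.grid_size))
    noise = ndimage.gaussian_filter(noise, 1.0, mode="wrap")
    noise = (noise - noise.mean()) / noise.std()
    speckle_ref = np.clip(1.0 + speckle_contrast * noise, 0.05, None)

    scales = _scales(cfg)
    trans = _translations_px(cfg)
    c = (cfg.grid_size - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(cfg.grid_size), np.arange(cfg.grid_size), indexing="ij")

    lo = min(cfg.wall_value, cfg.background_value, cfg.cavity_value,
             cfg.defect_value if cfg.defect_arc_deg is not None else cfg.wall_value)
    hi = max(cfg.wall_value, cfg.background_value, cfg.cavity_value)

    frames = []
    for k, (s, t) in enumerate(zip(scales, trans)):
        act = truth.hr_frames[k].data
        bright = np.sqrt((act - lo) / (hi - lo) if hi > lo else act * 0.0 + 0.5)
        if speckle_contrast > 0:
            # sample the reference texture at material coordinates of frame k
            ym = (yy - c - t) / s + c
            xm = (xx - c) / s + c
            tex = ndimage.map_coordinates(
                speckle_ref, np.stack([ym, xm]), order=1, mode="wrap"
            )
            bright = bright * tex
        frames.append(Image2D(bright, cfg.spacing_hr))
    return GatedSequence(frames)


def degrade_sequence(
    truth: PhantomTruth,
    psf: PSFModel,
    factor: int,
    counts_scale: float = 40.0,
    seed: int = 0,
    noise_model: str = "poisson",
) -> GatedSequence:
    """Gated low-resolution PET frames from the reference activity.

    Per frame: the reference high-resolution image is warped into the
    frame's geometry (with the negated pull-back field, the same
    approximate inverse the SR stage uses), decimated by ``factor``,
    blurred with the system PSF, and corrupted by count noise.

    ``counts_scale`` is the expected number of counts a pixel of unit
    activity accumulates; Poisson noise is rescaled back to activity
    units.  ``noise_model`` is ``'poisson'`` (default), ``'gaussian'``
    (additive, matching the Poisson variance) or ``'none'``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    if counts_scale <= 0:
        raise ValueError("counts_scale must be positive")
    if noise_model not in ("poisson", "gaussian", "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    ref = truth.reference
    frames = []
    for M in truth.true_mvfs:
        moved = warp_image(ref, invert_mvf(M))
        low = gaussian_blur(downsample(moved, int(factor)), psf)
        data = low.data
        if noise_model == "poisson":
            data = rng.poisson(np.clip(data, 0.0, None) * counts_scale) / counts_scale
        elif noise_model == "gaussian":
            sigma = np.sqrt(np.clip(data, 0.0, None) / counts_scale)
            data = data + rng.normal(0.0, 1.0, data.shape) * sigma
        frames.append(Image2D(data, low.spacing))
    return GatedSequence(frames)
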