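"""Variational intensity + local-phase motion registration.

Per-frame cardiac motion is estimated from the high-resolution
anatomical sequence by minimising, over a window around the ventricle,

    E(M) = 1/2 sum_x  k   [I_R(x) - I_T(x + M(x))]^2
                  + (1-k) [theta_R(x) - theta_T(x + M(x))]^2,

where ``theta`` is the monogenic local phase computed with a log-Gabor
even filter and its Riesz-transform odd pair,

    theta = atan( I_e / sqrt((F_o1 * I_e)^2 + (F_o2 * I_e)^2) ).

The phase term makes the match robust to local brightness changes
(speckle, shadowing); ``k`` balances the two data terms.  The descent
uses demons-style regularized forces for each term,

    f = (I_R - I_T o M) grad I_R / (|grad I_R|^2 + (I_R - I_T o M)^2),

additive corrections, fluid-like regularization (Gaussian smoothing of
each increment) and a coarse-to-fine pyramid with one band-pass
wavelength per level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import GatedSequence, Image2D, MotionField

__all__ = [
    "RegistrationConfig",
    "QuadratureBank",
    "log_gabor_bank",
    "local_phase",
    "fluid_smooth",
    "demons_update",
    "register_pair",
    "register_sequence",
    "registration_energy",
]


@dataclass
class RegistrationConfig:
    """Parameters of the multi-scale demons registration.

    ``wavelengths_px`` lists the log-Gabor centre wavelengths (pixels
    of each level's grid) from the coarsest to the finest pyramid
    level; its length must equal ``pyramid_levels``.  ``window`` is an
    optional ``(row_slice, col_slice)`` region on the full-resolution
    grid restricting the force computation; by default the whole image
    drives the match.
    """

    k: float = 0.5
    pyramid_levels: int = 3
    wavelengths_px: tuple[float, ...] = (16.0, 8.0, 2.0)
    iters_per_level: int = 10
    fluid_sigma_px: float = 10.0
    sigma_ratio: float = 0.55
    window: Optional[tuple[slice, slice]] = None
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must lie in [0, 1]")
        if len(self.wavelengths_px) != self.pyramid_levels:
            raise ValueError("one wavelength per pyramid level is required")
        if min(self.wavelengths_px) <= 0 or self.fluid_sigma_px <= 0:
            raise ValueError("scales must be positive")
        if self.iters_per_level < 1 or self.pyramid_levels < 1:
            raise ValueError("counts must be positive")


@dataclass
class QuadratureBank:
    """Frequency-domain quadrature filters for one band.

    ``even`` is the log-Gabor radial band-pass (real, zero DC); the
    odd pair is the Riesz multiplier applied to it (purely imaginary,
    antisymmetric, zero at DC).
    """

    even: np.ndarray
    odd1: np.ndarray
    odd2: np.ndarray
    center_wavelength_px: float


def log_gabor_bank(
    shape: Sequence[int], wavelength_px: float, sigma_ratio: float = 0.55
) -> QuadratureBank:
    """Log-Gabor even filter and Riesz odd pair on an FFT grid.

    The even filter peaks at spatial frequency ``1/wavelength_px`` and
    has a Gaussian profile on log-frequency with relative bandwidth
    ``sigma_ratio``.
    """
    if wavelength_px < 2.0:
        raise ValueError("wavelength must be at least 2 px (Nyquist)")
    if not 0.0 < sigma_ratio < 1.0:
        raise ValueError("sigma_ratio must lie in (0, 1)")
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    rho = np.hypot(fy, fx)
    rho0 = rho.copy()
    rho0[0, 0] = 1.0  # avoid log(0); DC is zeroed below
    f0 = 1.0 / wavelength_px
    even = np.exp(-(np.log(rho0 / f0) ** 2) / (2.0 * np.log(sigma_ratio) ** 2))
    even[0, 0] = 0.0
    riesz1 = 1j * fx / rho0
    riesz2 = 1j * fy / rho0
    riesz1[0, 0] = 0.0
    riesz2[0, 0] = 0.0
    return QuadratureBank(
        even=even,
        odd1=even * riesz1,
        odd2=even * riesz2,
        center_wavelength_px=float(wavelength_px),
    )


def local_phase(
    img: Image2D | np.ndarray, bank: QuadratureBank, epsilon: float = 1e-12
) -> np.ndarray:
    """Monogenic local phase in radians, values in (-pi/2, pi/2).

    ``epsilon`` (scaled by the squared dynamic range) guards the
    denominator where both odd responses vanish.
    """
    a = img.data if isinstance(img, Image2D) else np.asarray(img, dtype=float)
    F = np.fft.fft2(a)
    even = np.fft.ifft2(F * bank.even).real
    o1 = np.fft.ifft2(F * bank.odd1).real
    o2 = np.fft.ifft2(F * bank.odd2).real
    dyn = float(np.ptp(a))
    eps = epsilon * (dyn * dyn if dyn > 0 else 1.0)
    return np.arctan(even / np.sqrt(o1 * o1 + o2 * o2 + eps))


def fluid_smooth(field: MotionField, sigma_px: float) -> MotionField:
    """Gaussian fluid regularization of both components (replicated borders)."""
    if sigma_px <= 0:
        raise ValueError("sigma must be positive")
    u = ndimage.gaussian_filter(field.u, sigma_px, mode="nearest")
    v = ndimage.gaussian_filter(field.v, sigma_px, mode="nearest")
    return MotionField(u, v, field.spacing, field.frame_index)


def _warp_array(a: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    ny, nx = a.shape
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    return ndimage.map_coordinates(a, np.stack([rows + v, cols + u]), order=1, mode="nearest")


def _force(
    residual: np.ndarray, gy: np.ndarray, gx: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Regularized demons force for one data term (per-component)."""
    denom = gy * gy + gx * gx + residual * residual + eps
    return residual * gx / denom, residual * gy / denom


def demons_update(
    I_R: np.ndarray,
    I_T: np.ndarray,
    theta_R: np.ndarray,
    theta_T: np.ndarray,
    M: MotionField,
    cfg: RegistrationConfig,
    window: Optional[tuple[slice, slice]] = None,
) -> MotionField:
    """One additive demons iteration combining intensity and phase forces.

    The template image and phase are sampled at ``x + M(x)`` before
    differencing; the combined force (zeroed outside the window) is
    fluid-smoothed and added to ``M``.
    """
    if I_R.shape != I_T.shape or I_R.shape != M.shape:
        raise ValueError("images and field must share one grid")
    eps = cfg.epsilon
    warped_I = _warp_array(I_T, M.u, M.v)
    warped_th = _warp_array(theta_T, M.u, M.v)

    gIy, gIx = np.gradient(I_R)
    gTy, gTx = np.gradient(theta_R)

    fu = np.zeros_like(I_R)
    fv = np.zeros_like(I_R)
    if cfg.k > 0:
        du, dv = _force(I_R - warped_I, gIy, gIx, eps)
        fu += cfg.k * du
        fv += cfg.k * dv
    if cfg.k < 1:
        du, dv = _force(theta_R - warped_th, gTy, gTx, eps)
        fu += (1.0 - cfg.k) * du
        fv += (1.0 - cfg.k) * dv

    if window is not None:
        mask = np.zeros_like(I_R)
        mask[window] = 1.0
        fu *= mask
        fv *= mask

    inc = fluid_smooth(MotionField(fu, fv, M.spacing, M.frame_index), cfg.fluid_sigma_px)
    return MotionField(M.u + inc.u, M.v + inc.v, M.spacing, M.frame_index)


def registration_energy(
    I_R: np.ndarray,
    I_T: np.ndarray,
    theta_R: np.ndarray,
    theta_T: np.ndarray,
    M: MotionField,
    k: float,
    window: Optional[tuple[slice, slice]] = None,
) -> float:
    """Evaluate the matching energy E at a given field (for diagnostics)."""
    wI = _warp_array(I_T, M.u, M.v)
    wth = _warp_array(theta_T, M.u, M.v)
    e = k * (I_R - wI) ** 2 + (1.0 - k) * (theta_R - wth) ** 2
    if window is not None:
        e = e[window]
    return 0.5 * float(e.sum())


def _pyramid(a: np.ndarray, levels: int) -> list[np.ndarray]:
    """Gaussian pyramid, finest first: anti-alias blur then decimate by 2."""
    pyr = [a]
    for _ in range(levels - 1):
        sm = ndimage.gaussian_filter(pyr[-1], 1.0, mode="nearest")
        pyr.append(sm[::2, ::2])
    return pyr


def _upsample_field(u: np.ndarray, v: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear field upsampling between pyramid levels, components x2."""
    ny, nx = u.shape
    ty, tx = shape
    yy = np.linspace(0.0, ny - 1.0, ty)
    xx = np.linspace(0.0, nx - 1.0, tx)
    coords = np.stack(np.meshgrid(yy, xx, indexing="ij"))
    up = ndimage.map_coordinates(u, coords, order=1, mode="nearest") * (tx / nx)
    vp = ndimage.map_coordinates(v, coords, order=1, mode="nearest") * (ty / ny)
    return up, vp


def _normalize(a: np.ndarray) -> np.ndarray:
    dyn = np.ptp(a)
    if dyn == 0:
        return np.zeros_like(a)
    return (a - a.min()) / dyn


def _window_at_level(
    window: Optional[tuple[slice, slice]], level: int
) -> Optional[tuple[slice, slice]]:
    if window is None:
        return None
    f = 2**level
    def scale(s: slice) -> slice:
        start = None if s.start is None else s.start // f
        stop = None if s.stop is None else -(-s.stop // f)
        return slice(start, stop)
    return (scale(window[0]), scale(window[1]))


def register_pair(I_R: Image2D, I_T: Image2D, cfg: Optional[RegistrationConfig] = None) -> MotionField:
    """Estimate the field M with ``I_T(x + M(x)) ~= I_R(x)``.

    Both images are normalized to [0, 1] so ``k`` balances the
    intensity and phase terms independently of input brightness.
    Degenerate (constant) inputs return a zero field with a warning.
    """
    cfg = cfg or RegistrationConfig()
    if not I_R.same_grid(I_T):
        raise ValueError("reference and template must share one grid")
    R = _normalize(I_R.data)
    T = _normalize(I_T.data)
    if np.ptp(I_R.data) == 0 or np.ptp(I_T.data) == 0:
        warnings.warn("constant image: returning zero motion field", stacklevel=2)
        return MotionField.zero(I_R.shape, I_R.spacing)

    levels = cfg.pyramid_levels
    pyr_R = _pyramid(R, levels)
    pyr_T = _pyramid(T, levels)

    u = v = None
    for lvl in range(levels - 1, -1, -1):  # coarse -> fine
        Rl, Tl = pyr_R[lvl], pyr_T[lvl]
        if u is None:
            u = np.zeros_like(Rl)
            v = np.zeros_like(Rl)
        else:
            u, v = _upsample_field(u, v, Rl.shape)
        wavelength = cfg.wavelengths_px[levels - 1 - lvl]
        bank = log_gabor_bank(Rl.shape, wavelength, cfg.sigma_ratio)
        th_R = local_phase(Rl, bank, cfg.epsilon)
        th_T = local_phase(Tl, bank, cfg.epsilon)
        win = _window_at_level(cfg.window, lvl)
        M = MotionField(u, v, I_R.spacing * 2**lvl)
        for _ in range(cfg.iters_per_level):
            M = demons_update(Rl, Tl, th_R, th_T, M, cfg, window=win)
        u, v = M.u, M.v
    return MotionField(u, v, I_R.spacing)


def register_sequence(frames: GatedSequence, cfg: Optional[RegistrationConfig] = None) -> list[MotionField]:
    """Register every frame to frame 0 (the reference phase).

    Returns one field per frame; the first is identically zero.
    """
    cfg = cfg or RegistrationConfig()
    fields = [MotionField.zero(frames.shape, frames.spacing, 0)]
    for i in range(1, len(frames)):
        M = register_pair(frames[0], frames[i], cfg)
        M.frame_index = i
        fields.append(M)
    return fields
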