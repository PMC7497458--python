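"""Image-quality metrics: ROI statistics, SNR, Weber contrast, LSF resolution.

SNR (dB) = 10 log10(MEAN/STD) over an ROI; contrast is Weber's
fraction (MEAN_wall - MEAN_cav) / MEAN_cav; spatial resolution is the
mean FWHM of Gaussian fits to the mirrored profile points external to
the outer ventricle-wall edge, on five profiles crossing the wall
orthogonally (basal lateral, mid lateral, apical, mid septal, basal
septal).  The edge position comes from the anatomical reference, not
from the image under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage, optimize

from .core import Image2D

__all__ = [
    "ROI",
    "ProfileSpec",
    "QualityReport",
    "roi_stats",
    "snr_db",
    "weber_contrast",
    "lsf_fwhm",
    "sample_profile",
    "wall_resolution",
    "annulus_profiles",
    "quality_report",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

PROFILE_LABELS = ("basal lateral", "mid lateral", "apical", "mid septal", "basal septal")


@dataclass
class ROI:
    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class ProfileSpec:
    """A line crossing the wall orthogonally, in mm image coordinates.

    ``start``/``end`` are (y, x) positions; ``edge_mm`` is the distance
    from ``start`` to the external wall edge along the line; samples
    beyond it are the ones mirrored for the LSF fit.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    edge_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if np.allclose(self.start, self.end):
            raise ValueError("profile start and end coincide")
        length = float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))
        if not 0.0 < self.edge_mm < length:
            raise ValueError("edge must lie strictly between start and end")


def roi_stats(img: Image2D | np.ndarray, roi: ROI | np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation over the mask."""
    a = img.data if isinstance(img, Image2D) else np.asarray(img, dtype=float)
    mask = roi.mask if isinstance(roi, ROI) else np.asarray(roi, dtype=bool)
    if a.shape != mask.shape:
        raise ValueError("ROI mask does not match the image grid")
    vals = a[mask]
    if vals.size == 0:
        raise ValueError("ROI mask is empty")
    return float(vals.mean()), float(vals.std())


def snr_db(mean: float, std: float) -> float:
    """Signal-to-noise ratio in dB: 10 log10(mean/std)."""
    if mean < 0 or std < 0:
        raise ValueError("mean and std must be non-negative")
    if std == 0:
        return math.inf
    if mean == 0:
        return -math.inf
    return 10.0 * math.log10(mean / std)


def weber_contrast(mean_wall: float, mean_cav: float) -> float:
    """Weber's fraction (mean_wall - mean_cav) / mean_cav."""
    if mean_cav <= 0:
        raise ValueError("cavity/background mean must be positive")
    return (mean_wall - mean_cav) / mean_cav


def lsf_fwhm(
    profile: np.ndarray,
    spacing_mm: float,
    edge_index: int,
    max_nfev: int = 200,
) -> float:
    """FWHM (mm) of a Gaussian fitted to the mirrored external half-profile.

    The samples at and beyond ``edge_index`` (the external side of the
    wall) are mirrored about the edge to form a symmetric peak; a
    Gaussian with fixed centre plus constant offset is least-squares
    fitted and its FWHM returned.  Degenerate data (flat tail, zero
    fitted amplitude or non-convergence) yields NaN.
    """
    profile = np.asarray(profile, dtype=float)
    if not 0 < edge_index < profile.size - 2:
        raise ValueError("edge_index must leave at least 3 external points")
    ext = profile[edge_index:]
    if ext.size < 3:
        raise ValueError("need at least 3 points external to the edge")
    d = np.arange(ext.size) * spacing_mm
    # mirroring about the edge duplicates every off-centre point
    dd = np.concatenate([-d[:0:-1], d])
    yy = np.concatenate([ext[:0:-1], ext])

    amp0 = float(ext[0] - ext.min())
    if amp0 <= 0 or np.ptp(ext) < 1e-12 * max(1.0, abs(ext[0])):
        return math.nan

    def model(x: np.ndarray, a: float, s: float, c: float) -> np.ndarray:
        return a * np.exp(-(x * x) / (2.0 * s * s)) + c

    p0 = (amp0, 2.0 * spacing_mm, float(ext.min()))
    try:
        popt, _ = optimize.curve_fit(
            model, dd, yy, p0=p0, maxfev=max_nfev,
            bounds=([0.0, 1e-6 * spacing_mm, -np.inf], [np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return math.nan
    a, s, _ = popt
    if a <= 0 or not np.isfinite(s):
        return math.nan
    return float(_FWHM * s)


def sample_profile(
    img: Image2D, spec: ProfileSpec, step_mm: Optional[float] = None
) -> tuple[np.ndarray, float, int]:
    """Sample an image along a profile line by bilinear interpolation.

    Returns the samples, the sampling step (mm) and the index of the
    sample nearest to the wall edge.
    """
    step = step_mm or img.spacing
    y0, x0 = spec.start
    y1, x1 = spec.end
    length = float(np.hypot(y1 - y0, x1 - x0))
    n = max(int(round(length / step)) + 1, 2)
    t = np.linspace(0.0, length, n)
    ys = (y0 + (y1 - y0) * t / length) / img.spacing
    xs = (x0 + (x1 - x0) * t / length) / img.spacing
    vals = ndimage.map_coordinates(img.data, np.stack([ys, xs]), order=1, mode="nearest")
    edge_index = int(round(spec.edge_mm / (length / (n - 1))))
    return vals, length / (n - 1), edge_index


def wall_resolution(
    img: Image2D,
    profiles: Sequence[ProfileSpec],
    max_failures: int = 2,
) -> tuple[float, list[float]]:
    """Mean LSF FWHM (mm) over the wall profiles.

    Each profile is sampled bilinearly, the external samples are fitted
    per :func:`lsf_fwhm`, and the per-profile FWHMs are averaged.  More
    than ``max_failures`` failed fits yields NaN.
    """
    fwhms: list[float] = []
    for spec in profiles:
        vals, step, edge = sample_profile(img, spec)
        try:
            f = lsf_fwhm(vals, step, edge)
        except ValueError:
            f = math.nan
        fwhms.append(f)
    ok = [f for f in fwhms if not math.isnan(f)]
    if len(fwhms) - len(ok) > max_failures:
        return math.nan, fwhms
    return float(np.mean(ok)), fwhms


def annulus_profiles(
    center_mm: tuple[float, float],
    outer_radius_mm: float,
    inner_radius_mm: float,
    tail_mm: float = 2.0,
    angles_deg: Optional[Sequence[float]] = None,
) -> list[ProfileSpec]:
    """Five radial profiles crossing an annular wall orthogonally.

    Each runs from mid-cavity out to ``outer_radius + tail_mm``; the
    external edge position is the outer radius (taken from the
    anatomical truth).  Angles default to five sites spread around the
    ring, mimicking the basal-lateral .. basal-septal sampling.
    """
    if angles_deg is None:
        angles_deg = (18.0, 90.0, 162.0, 234.0, 306.0)
    r0 = inner_radius_mm / 2.0
    specs = []
    for ang, label in zip(angles_deg, PROFILE_LABELS):
        a = math.radians(ang)
        dy, dx = math.sin(a), math.cos(a)
        start = (center_mm[0] + r0 * dy, center_mm[1] + r0 * dx)
        r1 = outer_radius_mm + tail_mm
        end = (center_mm[0] + r1 * dy, center_mm[1] + r1 * dx)
        specs.append(ProfileSpec(start=start, end=end, edge_mm=outer_radius_mm - r0, label=label))
    return specs


@dataclass
class QualityReport:
    """Per-image quality rows plus pairwise percent improvements."""

    rows: dict[str, dict[str, float]]
    improvements: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows).T

    def to_dict(self) -> dict:
        return {"rows": self.rows, "improvements": self.improvements}


def _row(
    img: Image2D,
    wall: ROI,
    cavity: ROI,
    profiles: Optional[Sequence[ProfileSpec]],
    lesion: Optional[ROI] = None,
) -> dict[str, float]:
    wm, ws = roi_stats(img, wall)
    cm, cs = roi_stats(img, cavity)
    row = {
        "wall_mean": wm,
        "wall_std": ws,
        "cavity_mean": cm,
        "cavity_std": cs,
        "contrast": weber_contrast(wm, cm),
        "snr_db": snr_db(wm, ws),
    }
    if lesion is not None:
        lm, ls = roi_stats(img, lesion)
        row["lesion_mean"] = lm
        row["lesion_std"] = ls
    if profiles is not None:
        res, fwhms = wall_resolution(img, profiles)
        row["resolution_mm"] = res
        for spec, f in zip(profiles, fwhms):
            row[f"lsf_{spec.label.replace(' ', '_')}_mm"] = f
    return row


def quality_report(
    images: Mapping[str, Image2D],
    wall: ROI,
    cavity: ROI,
    profiles: Optional[Sequence[ProfileSpec]] = None,
    lesion: Optional[ROI] = None,
) -> QualityReport:
    """Quality rows for each named image (all must share the reference grid).

    ``images`` typically holds ``gated_frame1``, ``static``, ``moco``
    and ``sr``; low-resolution inputs should be upsampled to the
    reference grid beforehand so every row uses identical masks.
    Percent improvements of contrast, SNR and resolution are reported
    for SR and MoCo against the static baseline.
    """
    rows = {name: _row(img, wall, cavity, profiles, lesion) for name, img in images.items()}
    improvements: dict[str, dict[str, float]] = {}
    if "static" in rows:
        base = rows["static"]
        for name in ("moco", "sr"):
            if name not in rows:
                continue
            imp: dict[str, float] = {}
            for key, better_low in (("contrast", False), ("snr_db", False), ("resolution_mm", True)):
                if key not in rows[name] or key not in base:
                    continue
                b, val = base[key], rows[name][key]
                if b == 0 or math.isnan(b) or math.isnan(val):
                    continue
                change = 100.0 * (b - val) / abs(b) if better_low else 100.0 * (val - b) / abs(b)
                imp[key + "_pct"] = change
            improvements[f"{name}_vs_static"] = imp
    return QualityReport(rows=rows, improvements=improvements)
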