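"""Core containers shared by all stages.

Images are 2-D scalar fields on regular grids with a physical pixel
spacing in mm.  PET frames carry SUV-like activity values; anatomical
(B-mode-like) frames carry arbitrary brightness.  Displacement fields
are expressed in pixels of the grid they live on, with ``u`` the
column (x) component and ``v`` the row (y) component; ``warp`` and all
consumers use the pull-back convention ``out(x) = img(x + M(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Image2D", "GatedSequence", "MotionField", "PSFModel"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class Image2D:
    """A scalar image on a regular grid.

    Parameters
    ----------
    data:
        2-D float array, row-major (y, x).
    spacing:
        Physical pixel size in mm (isotropic).
    """

    data: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"Image2D expects a 2-D array, got {self.data.ndim}-D")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "Image2D":
        return Image2D(self.data.copy(), self.spacing)

    def same_grid(self, other: "Image2D") -> bool:
        return self.shape == other.shape and np.isclose(self.spacing, other.spacing)


@dataclass
class GatedSequence:
    """Ordered frames covering one cardiac cycle uniformly.

    Frame 0 is the reference phase (end-diastole).
    """

    frames: list[Image2D]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("GatedSequence needs at least one frame")
        sp = self.frames[0].spacing
        sh = self.frames[0].shape
        for f in self.frames:
            if f.shape != sh or not np.isclose(f.spacing, sp):
                raise ValueError("all frames must share one grid")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Image2D:
        return self.frames[i]

    def __iter__(self) -> Iterator[Image2D]:
        return iter(self.frames)

    @property
    def spacing(self) -> float:
        return self.frames[0].spacing

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        """Stack frames into a (n_frames, ny, nx) array."""
        return np.stack([f.data for f in self.frames])

    @classmethod
    def from_array(cls, arr: np.ndarray, spacing: float) -> "GatedSequence":
        return cls([Image2D(a, spacing) for a in np.asarray(arr, dtype=np.float64)])


@dataclass
class MotionField:
    """Per-pixel 2-D displacement aligning one frame to the reference.

    ``u``/``v`` are the x (column) and y (row) displacement components
    in pixels of the grid the field lives on.  For the stored field
    ``M_i`` of frame *i*, sampling frame *i* at ``x + M_i(x)``
    reconstructs the reference frame (pull-back warping).  The negated
    field serves as the approximate inverse.
    """

    u: np.ndarray
    v: np.ndarray
    spacing: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2-D arrays of identical shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacement components must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def copy(self) -> "MotionField":
        return MotionField(self.u.copy(), self.v.copy(), self.spacing, self.frame_index)

    @classmethod
    def zero(cls, shape: Sequence[int], spacing: float, frame_index: int = 0) -> "MotionField":
        z = np.zeros(tuple(shape), dtype=np.float64)
        return cls(z, z.copy(), spacing, frame_index)


@dataclass(frozen=True)
class PSFModel:
    """Isotropic Gaussian system point-spread function.

    The width is physical (mm) so the blur a grid sees depends on its
    pixel spacing; ``fwhm_mm = 0`` denotes a delta (no blur).
    """

    fwhm_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be non-negative")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm / _FWHM_TO_SIGMA

    def sigma_px(self, spacing: float) -> float:
        """Gaussian sigma in pixels on a grid with the given spacing (mm)."""
        return self.sigma_mm / spacing

    @property
    def is_delta(self) -> bool:
        return self.fwhm_mm == 0.0
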