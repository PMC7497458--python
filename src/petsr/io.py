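"""Reading and writing gated stacks, motion fields and masks.

Gated sequences travel as multi-page TIFF (spacing in the resolution
tags, unit mm) or NIfTI-1 (spacing in the affine); motion fields as
2-channel stacks (u then v per frame); masks as 8-bit label images.
Round-trips preserve values to 32-bit float precision and spacing
exactly.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .core import GatedSequence, Image2D, MotionField

__all__ = [
    "read_stack",
    "write_stack",
    "read_fields",
    "write_fields",
    "write_mask",
    "read_mask",
]

_TIFF_EXT = (".tif", ".tiff")
_NIFTI_EXT = (".nii", ".nii.gz")


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def _write_tiff(path: str, arr: np.ndarray, spacing: float) -> None:
    import tifffile

    tifffile.imwrite(
        path,
        arr.astype(np.float32),
        photometric="minisblack",
        resolution=(1.0 / spacing, 1.0 / spacing),
        metadata={"spacing_mm": spacing},
    )


def _read_tiff(path: str) -> tuple[np.ndarray, Optional[float]]:
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        spacing = None
        page = tf.pages[0]
        # spacing is carried exactly in the shaped-description metadata;
        # fall back to the resolution tags for stacks written elsewhere
        desc = page.description or ""
        if "spacing_mm" in desc:
            try:
                spacing = float(json.loads(desc)["spacing_mm"])
            except (ValueError, KeyError, TypeError):
                spacing = None
        if spacing is None:
            tag = page.tags.get("XResolution")
            if tag is not None:
                num, den = tag.value
                if num and (num, den) != (1, 1):
                    spacing = den / num
    return np.asarray(arr), spacing


def _write_nifti(path: str, arr: np.ndarray, spacing: float) -> None:
    import nibabel as nib

    # store frames along the third axis; spacing on the in-plane axes
    data = np.moveaxis(arr.astype(np.float32), 0, -1) if arr.ndim == 3 else arr.astype(np.float32)
    affine = np.diag([spacing, spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)


def _read_nifti(path: str) -> tuple[np.ndarray, Optional[float]]:
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)
    spacing = float(img.affine[0, 0])
    return data, abs(spacing) if spacing else None


def write_stack(seq: GatedSequence, path: str) -> None:
    """Write a gated sequence as a multi-page TIFF or NIfTI-1 stack."""
    arr = seq.as_array()
    if _is_nifti(path):
        _write_nifti(path, arr, seq.spacing)
    elif path.lower().endswith(_TIFF_EXT):
        _write_tiff(path, arr, seq.spacing)
    else:
        raise ValueError(f"unsupported stack format: {path}")


def read_stack(path: str, spacing: Optional[float] = None) -> GatedSequence:
    """Read a gated sequence; ``spacing`` overrides/supplies missing metadata."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_nifti(path):
        arr, sp = _read_nifti(path)
    elif path.lower().endswith(_TIFF_EXT):
        arr, sp = _read_tiff(path)
    else:
        raise ValueError(f"unsupported stack format: {path}")
    sp = spacing if spacing is not None else sp
    if sp is None:
        raise ValueError(f"{path} carries no pixel spacing; pass spacing= explicitly")
    if arr.ndim == 2:
        arr = arr[None]
    return GatedSequence.from_array(arr, float(sp))


def write_fields(mvfs: list[MotionField], path: str) -> None:
    """Write motion fields as a (2*n, ny, nx) stack: u then v per frame."""
    arr = np.stack([c for M in mvfs for c in (M.u, M.v)])
    if _is_nifti(path):
        _write_nifti(path, arr, mvfs[0].spacing)
    elif path.lower().endswith(_TIFF_EXT):
        _write_tiff(path, arr, mvfs[0].spacing)
    else:
        raise ValueError(f"unsupported field format: {path}")


def read_fields(path: str, spacing: Optional[float] = None) -> list[MotionField]:
    seq = read_stack(path, spacing=spacing)
    arr = seq.as_array()
    if arr.shape[0] % 2:
        raise ValueError("field stack must hold an even number of pages (u, v pairs)")
    out = []
    for i in range(arr.shape[0] // 2):
        out.append(MotionField(arr[2 * i], arr[2 * i + 1], seq.spacing, i))
    return out


def write_mask(mask: np.ndarray, path: str, spacing: float) -> None:
    """Write a boolean/label mask as an 8-bit image."""
    import tifffile

    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8),
                     photometric="minisblack",
                     resolution=(1.0 / spacing, 1.0 / spacing))


def read_mask(path: str) -> np.ndarray:
    arr, _ = _read_tiff(path)
    return arr.astype(np.uint8)
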