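"""Standardise anatomical volumes into fixed slabs: 200 x 224 x 224 x 3.

A raw 3D acquisition arrives with an arbitrary slice count and in-plane
matrix. The slab pipeline makes every subject comparable:

1. slice-count standardisation — volumes with more than ``target_slices``
   keep the contiguous central window; volumes with fewer get zero-valued
   ("blank") slices padded symmetrically, the odd extra slice at the back;
2. per-slice bilinear resize to 224 x 224 (anti-aliased when
   downscaling);
3. intensity normalisation — per-volume division by the maximum over
   brain (non-zero) voxels, so values land in [0, 1]; switchable off;
4. channel replication — the single grayscale channel is copied onto
   three identical channels, matching the RGB contract of 2D backbones.

The slice axis is taken from the NIfTI orientation metadata (the
inferior-superior axis), falling back to axis 0 with a warning when the
orientation is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = ["SlabStack", "standardize_slice_count", "resize_slice", "to_three_channel",
           "preprocess_volume", "preprocess_array", "infer_slice_axis",
           "TARGET_SLICES", "TARGET_SIZE"]

logger = logging.getLogger(__name__)

TARGET_SLICES = 200
TARGET_SIZE = 224


@dataclass
class SlabStack:
    """A standardised volume: ``data`` is (slices, size, size, 3) float32."""

    data: np.ndarray
    slice_axis: int
    pad_front: int
    pad_back: int
    source_id: str = ""

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError(f"SlabStack data must be (slices, h, w, 3), got {self.data.shape}")
        if abs(self.pad_front - self.pad_back) > 1:
            raise ValueError(f"padding must be symmetric within 1 slice, "
                             f"got ({self.pad_front}, {self.pad_back})")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


def standardize_slice_count(volume: np.ndarray, target: int = TARGET_SLICES
                            ) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop the central window or pad blank slices along axis 0.

    Returns ``(volume, (pad_front, pad_back))``; pads are (0, 0) when the
    volume was cropped or already at target. For an odd deficit the extra
    blank slice goes at the back.
    """
    if target <= 0:
        raise ValueError(f"target slice count must be positive, got {target}")
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    native = volume.shape[0]
    if native == target:
        return volume, (0, 0)
    if native > target:
        start = (native - target) // 2
        return volume[start:start + target], (0, 0)
    deficit = target - native
    front, back = deficit // 2, deficit - deficit // 2
    padded = np.zeros((target,) + volume.shape[1:], dtype=volume.dtype)
    padded[front:front + native] = volume
    return padded, (front, back)


def resize_slice(slice2d: np.ndarray, size: int = TARGET_SIZE) -> np.ndarray:
    """Bilinear resize of one slice to ``size x size``.

    Anti-aliasing is applied when downscaling; a slice already at target
    size passes through unchanged.
    """
    if slice2d.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {slice2d.shape}")
    if slice2d.shape == (size, size):
        return np.asarray(slice2d, dtype=np.float64)
    down = slice2d.shape[0] > size or slice2d.shape[1] > size
    return _sk_resize(slice2d.astype(np.float64), (size, size), order=1,
                      anti_aliasing=down, preserve_range=True, mode="reflect")


def to_three_channel(slice2d: np.ndarray) -> np.ndarray:
    """Copy a single-channel slice onto three identical channels."""
    if slice2d.ndim != 2:
        raise ValueError(f"expected a single-channel 2D slice, got shape {slice2d.shape}")
    return np.repeat(slice2d[:, :, None], 3, axis=2)


def infer_slice_axis(img: "nib.Nifti1Image") -> int:
    """Array axis pointing inferior-superior per the affine; axis 0 fallback."""
    try:
        codes = nib.aff2axcodes(img.affine)
    except Exception:  # noqa: BLE001 - malformed affine
        codes = None
    if codes is not None:
        for axis, code in enumerate(codes):
            if code in ("S", "I"):
                return axis
    logger.warning("could not identify the inferior-superior axis from the affine; "
                   "falling back to axis 0")
    return 0


def preprocess_array(volume: np.ndarray, source_id: str = "",
                     target_slices: int = TARGET_SLICES, size: int = TARGET_SIZE,
                     normalize: str = "max") -> SlabStack:
    """Slab pipeline on an in-memory volume (slice axis already first)."""
    if normalize not in ("max", "none"):
        raise ValueError(f"normalize must be 'max' or 'none', got {normalize!r}")
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}; "
                         "select a single 3D volume from 4D inputs")
    std, (front, back) = standardize_slice_count(volume, target_slices)

    # Vectorised per-slice bilinear resize of the non-blank band only: sigma 0
    # along the slice axis, so no intensity ever leaks between slices and the
    # blank padding stays exact zero.
    h, w = std.shape[1], std.shape[2]
    band = std[front:target_slices - back].astype(np.float64)
    if (h, w) != (size, size):
        sy, sx = size / h, size / w
        sig = (0.0, max(0.0, (1 / sy - 1) / 2), max(0.0, (1 / sx - 1) / 2))
        if sig[1] > 0 or sig[2] > 0:                 # anti-alias when downscaling
            band = ndimage.gaussian_filter(band, sigma=sig, mode="reflect")
        band = ndimage.zoom(band, (1.0, sy, sx), order=1, grid_mode=True,
                            mode="grid-constant")

    if normalize == "max":
        peak = band.max() if band.size else 0.0
        if peak > 0:
            band /= peak
    data = np.zeros((target_slices, size, size, 3), dtype=np.float32)
    data[front:target_slices - back] = band[:, :, :, None]
    return SlabStack(data=data, slice_axis=0, pad_front=front, pad_back=back,
                     source_id=source_id)


def preprocess_volume(path: str | Path, target_slices: int = TARGET_SLICES,
                      size: int = TARGET_SIZE, normalize: str = "max") -> SlabStack:
    """Read a NIfTI file and run the full slab pipeline.

    The inferior-superior axis (from the orientation metadata) becomes the
    slice axis. 4D inputs are rejected with guidance; unreadable files
    raise an I/O error naming the path.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - nibabel raises various types
        raise OSError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} has shape {data.shape}; select a single 3D volume "
                         "(e.g. one timepoint of a 4D series)")
    axis = infer_slice_axis(img)
    data = np.moveaxis(data, axis, 0)
    stack = preprocess_array(data, source_id=path.name, target_slices=target_slices,
                             size=size, normalize=normalize)
    stack.slice_axis = axis
    return stack
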