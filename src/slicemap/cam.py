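"""Activation mapping: where on a slice the frozen backbone responds.

The map is the channel mean of the extractor's last convolutional
activation, bilinearly upsampled to the slice resolution and min-max
normalised to [0, 1]. A constant activation (e.g. on a blank padded
slice with a bias-free backbone) has no contrast to normalise and maps
to all zeros by convention. Overlays blend the colormapped heatmap onto
the grayscale slice and are the standard visual check that extraction
attends to brain tissue rather than background or padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

from .features import Extractor

__all__ = ["Heatmap", "compute_cam", "overlay"]


@dataclass
class Heatmap:
    values: np.ndarray           # (H, W), each in [0, 1]
    source_slice_index: int = -1
    source_subject: str = ""

    def __post_init__(self):
        v = self.values
        if v.ndim != 2:
            raise ValueError(f"heatmap must be 2D, got shape {v.shape}")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


def compute_cam(extractor: Extractor, slice3: np.ndarray,
                source_slice_index: int = -1, source_subject: str = "") -> Heatmap:
    """Channel-averaged last-conv activation, upsampled and normalised."""
    if not hasattr(extractor, "last_conv_activation"):
        raise TypeError("extractor exposes no convolutional activation; "
                        "activation mapping requires a convolutional backbone")
    act = extractor.last_conv_activation(slice3)     # (h, w, C)
    m = act.mean(axis=2)
    size = slice3.shape[0], slice3.shape[1]
    m = _sk_resize(m, size, order=1, preserve_range=True, mode="reflect")
    lo, hi = float(m.min()), float(m.max())
    values = np.zeros(size) if hi == lo else (m - lo) / (hi - lo)
    return Heatmap(values=np.clip(values, 0.0, 1.0),
                   source_slice_index=source_slice_index, source_subject=source_subject)


def _gray_rgb(slice2d: np.ndarray) -> np.ndarray:
    lo, hi = float(slice2d.min()), float(slice2d.max())
    g = np.zeros_like(slice2d, dtype=np.float64) if hi == lo else (slice2d - lo) / (hi - lo)
    return np.repeat(g[:, :, None], 3, axis=2)


def colormapped(values: np.ndarray, cmap: str = "viridis") -> np.ndarray:
    from matplotlib import colormaps
    return np.asarray(colormaps[cmap](values))[:, :, :3]


def overlay(heatmap: Heatmap, slice2d: np.ndarray, alpha: float = 0.4,
            out_path=None, cmap: str = "viridis") -> np.ndarray:
    """Blend ``alpha`` of the colormapped heatmap onto the grayscale slice.

    Returns the blended image as uint8 RGB; writes a PNG when ``out_path``
    is given. ``alpha=0`` reproduces the grayscale slice, ``alpha=1`` the
    colormapped heatmap.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if heatmap.values.shape != slice2d.shape:
        raise ValueError(f"heatmap shape {heatmap.values.shape} does not match "
                         f"slice shape {slice2d.shape}")
    blend = (1.0 - alpha) * _gray_rgb(slice2d) + alpha * colormapped(heatmap.values, cmap)
    img = np.round(np.clip(blend, 0.0, 1.0) * 255.0).astype(np.uint8)
    if out_path is not None:
        Image.fromarray(img).save(str(out_path))
    return img
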