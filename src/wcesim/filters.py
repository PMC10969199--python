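"""Sharpen / detail convolution preprocessing.

Both filters are fixed 3x3 kernels applied per channel with
edge-replicate padding, then clipped to [0, 255] and rounded.  The kernel
constants are part of this module's contract so behaviour is
bit-reproducible regardless of any imaging library's internals:

* sharpen: [[-2,-2,-2],[-2,32,-2],[-2,-2,-2]] / 16
* detail:  [[0,-1,0],[-1,10,-1],[0,-1,0]] / 6

Each kernel sums to its scale, so constant images are fixed points.
``sharpen_detail`` composes sharpen first, then detail.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve

from .io import validate_rgb

SHARPEN_KERNEL = np.array(
    [[-2.0, -2.0, -2.0], [-2.0, 32.0, -2.0], [-2.0, -2.0, -2.0]]
) / 16.0

DETAIL_KERNEL = np.array(
    [[0.0, -1.0, 0.0], [-1.0, 10.0, -1.0], [0.0, -1.0, 0.0]]
) / 6.0

FILTER_NAMES = ("none", "sharpen", "detail", "sharpen_detail")


def _convolve_rgb(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    arr = validate_rgb(image).astype(np.float64)
    out = np.empty_like(arr)
    for c in range(3):
        # mode="nearest" is edge-replicate padding
        out[..., c] = convolve(arr[..., c], kernel, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def sharpen(image: np.ndarray) -> np.ndarray:
    """Amplify the centre against its 8-neighbourhood."""
    return _convolve_rgb(image, SHARPEN_KERNEL)


def detail(image: np.ndarray) -> np.ndarray:
    """Milder 4-neighbourhood contrast boost.  Not idempotent."""
    return _convolve_rgb(image, DETAIL_KERNEL)


def sharpen_detail(image: np.ndarray) -> np.ndarray:
    """sharpen, then detail (fixed composition order)."""
    return detail(sharpen(image))


def apply_filter(image: np.ndarray, name: str) -> np.ndarray:
    """Dispatch by filter name; "none" is the identity."""
    if name == "none":
        return validate_rgb(image)
    if name == "sharpen":
        return sharpen(image)
    if name == "detail":
        return detail(image)
    if name == "sharpen_detail":
        return sharpen_detail(image)
    raise ValueError(f"unknown filter {name!r}; known: {FILTER_NAMES}")
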