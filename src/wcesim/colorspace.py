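"""RGB <-> l-alpha-beta conversion and per-channel statistics.

The l-alpha-beta space (Ruderman's opponent space, as used by Reinhard-style
statistical color transfer) decorrelates natural-image color channels:
``l`` is achromatic, ``alpha`` opposes yellow-blue, ``beta`` opposes
red-green.  The forward path is RGB -> LMS (linear 3x3 map) -> log10 ->
fixed decorrelation map with diagonal scalings (1/sqrt(3), 1/sqrt(6),
1/sqrt(2)).  Intensities are normalised to [0, 1] and floored at 1/255
before the log so pure black stays finite.

Per-channel means and standard deviations in this space are the sufficient
statistics of moment-matching color transfer; :class:`ChannelStats` holds
them.  The SD is the population SD (ddof=0) — fixed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

# Reinhard-publication RGB->LMS matrix.
RGB_TO_LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)

# Ruderman decorrelation of log-LMS into l, alpha, beta.
LOGLMS_TO_LAB = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)]) @ np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, 1.0, -2.0],
        [1.0, -1.0, 0.0],
    ]
)

LMS_TO_RGB = np.linalg.inv(RGB_TO_LMS)
LAB_TO_LOGLMS = np.linalg.inv(LOGLMS_TO_LAB)

# Floor on normalised intensities: the darkest representable level.
INTENSITY_FLOOR = 1.0 / 255.0


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel (l, alpha, beta) mean and population SD."""

    mean_l: float
    mean_alpha: float
    mean_beta: float
    sd_l: float
    sd_alpha: float
    sd_beta: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValidationError("n_pixels must be >= 1")
        if min(self.sd_l, self.sd_alpha, self.sd_beta) < 0:
            raise ValidationError("standard deviations must be nonnegative")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_l, self.mean_alpha, self.mean_beta])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_l, self.sd_alpha, self.sd_beta])

    @classmethod
    def from_arrays(cls, means: np.ndarray, sds: np.ndarray, n_pixels: int) -> "ChannelStats":
        return cls(*(float(m) for m in means), *(float(s) for s in sds), int(n_pixels))

    def to_dict(self) -> dict:
        return {
            "mean": [self.mean_l, self.mean_alpha, self.mean_beta],
            "sd": [self.sd_l, self.sd_alpha, self.sd_beta],
            "n_pixels": self.n_pixels,
        }


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an RGB array (uint8 or float in [0,255]) to an HxWx3 lab array."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 image, got shape {arr.shape}")
    x = np.maximum(arr / 255.0, INTENSITY_FLOOR)
    lms = x @ RGB_TO_LMS.T
    # Rows of RGB_TO_LMS are positive, so lms >= floor * min(row sum) > 0.
    log_lms = np.log10(lms)
    return log_lms @ LOGLMS_TO_LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_lab`; clip to gamut and round to uint8."""
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 lab array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValidationError("lab array contains non-finite values")
    log_lms = arr @ LAB_TO_LOGLMS.T
    lms = np.power(10.0, log_lms)
    rgb = lms @ LMS_TO_RGB.T
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def near_black_mask(image: np.ndarray, threshold: int = 10) -> np.ndarray:
    """Boolean plane selecting pixels whose max channel >= ``threshold``.

    Endoscopy frames carry a circular black border; excluding it keeps the
    border from dominating channel statistics.
    """
    arr = np.asarray(image)
    return arr.max(axis=2) >= threshold


def channel_stats(lab: np.ndarray, mask: np.ndarray | None = None) -> ChannelStats:
    """Mean and population SD per lab channel, optionally over a pixel mask."""
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 lab array, got shape {arr.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape[:2]:
            raise ValidationError(f"mask shape {mask.shape} != image plane {arr.shape[:2]}")
        if not mask.any():
            raise ValidationError("mask selects no pixels")
        pix = arr[mask]
    else:
        pix = arr.reshape(-1, 3)
    means = pix.mean(axis=0)
    sds = pix.std(axis=0, ddof=0)
    return ChannelStats.from_arrays(means, sds, pix.shape[0])
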