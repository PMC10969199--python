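"""Geometric augmentation and class balancing.

The variant budget per source image is the product set
{identity, hflip, vflip, hflip+vflip} x {no rotation, +20 deg, -20 deg}
minus nothing (the pure identity is variant 0, the original), i.e. 12
distinct variants.  Flips are pixel-exact involutions; rotations use
bilinear resampling on the original canvas with black fill, matching the
dark borders of endoscopy frames.

``balance_class`` expands a class to an exact target count: all originals
first, then variants allocated in rounds (every source receives its k-th
variant before any source receives its (k+1)-th) with the final partial
round drawn by seeded sampling without replacement.  Hence
variants-per-source never differs by more than one across sources, and no
(source, chain) pair repeats.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .errors import CapacityError, ValidationError
from .io import ManifestRecord, validate_rgb

TILT_DEGREES = 20.0

_FLIP_SETS: list[tuple[str, ...]] = [(), ("hflip",), ("vflip",), ("hflip", "vflip")]
_ROT_SETS: list[tuple[str, ...]] = [(), ("rot+20",), ("rot-20",)]

#: Canonical variant catalogue; index 0 is the original (empty chain).
VARIANTS: list[tuple[str, ...]] = [f + r for f in _FLIP_SETS for r in _ROT_SETS]

VARIANT_BUDGET = len(VARIANTS)  # 12


def chain_slug(chain: Sequence[str]) -> str:
    """Filesystem-safe name for a transform chain ('orig' when empty)."""
    if not chain:
        return "orig"
    return "-".join(t.replace("+", "p").replace("-", "m", 1) if t.startswith("rot") else t for t in chain)


def apply_transform(image: np.ndarray, chain: Sequence[str]) -> np.ndarray:
    """Apply a transform chain in order; output keeps the input canvas size."""
    arr = validate_rgb(image)
    out = arr
    for name in chain:
        if name == "hflip":  # left-right inversion
            out = out[:, ::-1, :]
        elif name == "vflip":  # top-down inversion
            out = out[::-1, :, :]
        elif name in ("rot+20", "rot-20"):
            angle = TILT_DEGREES if name == "rot+20" else -TILT_DEGREES
            rotated = _sk_rotate(
                out.astype(np.float64),
                angle,
                resize=False,
                order=1,
                mode="constant",
                cval=0.0,
                preserve_range=True,
            )
            out = np.clip(np.rint(rotated), 0, 255).astype(np.uint8)
        else:
            raise ValidationError(f"unknown transform {name!r}")
    return np.ascontiguousarray(out)


def balance_class(
    records: Sequence[ManifestRecord],
    target_count: int,
    seed: int = 0,
) -> list[tuple[ManifestRecord, tuple[str, ...]]]:
    """Plan an exact-count expansion of one class.

    Returns ``target_count`` unique ``(record, chain)`` pairs in a
    deterministic order (sorted by source path, then variant index).  Only
    the plan is produced; materialising the images is the caller's job, so
    counting and splitting never require pixel work.
    """
    if len(records) == 0:
        raise ValidationError("class has no source records")
    n = len(records)
    if target_count > n * VARIANT_BUDGET:
        raise CapacityError(
            f"target {target_count} exceeds capacity {n * VARIANT_BUDGET} "
            f"({n} sources x {VARIANT_BUDGET} variants)"
        )
    if target_count < 0:
        raise ValidationError("target_count must be nonnegative")
    ordered = sorted(records, key=lambda r: r.image_path)
    full_rounds = target_count // n
    remainder = target_count % n
    chosen: list[tuple[int, int]] = []  # (source index, variant index)
    for k in range(full_rounds):
        chosen.extend((i, k) for i in range(n))
    if remainder:
        rng = np.random.default_rng(seed)
        extra = rng.choice(n, size=remainder, replace=False)
        chosen.extend((int(i), full_rounds) for i in extra)
    chosen.sort()
    return [(ordered[i], VARIANTS[k]) for i, k in chosen]
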