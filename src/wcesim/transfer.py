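"""Statistical (Reinhard-style) color transfer.

The transfer is a per-channel affine moment match in l-alpha-beta space:
for each channel ``k``,

    out_k = (sd_target_k / sd_source_k) * (source_k - mean(source_k)) + mean(target_k)

so the result's channel means and SDs equal the target's exactly (before
the final clip back to the RGB gamut).  Geometry is untouched; only color
statistics move.  If a source channel is constant (sd = 0, up to float
round-off) the output channel is the constant target mean.

An ``space="rgb"`` mode applies the same affine match directly to the R, G,
B channels for comparison; the lab route is the default because the
decorrelated channels transfer independently without cross-channel
artefacts.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .colorspace import ChannelStats, channel_stats, lab_to_rgb, near_black_mask, rgb_to_lab
from .errors import ValidationError
from .io import DatasetManifest, ManifestRecord, load_image, save_image


def _stats_of(image: np.ndarray, space: str, mask_policy: str) -> ChannelStats:
    mask = near_black_mask(image) if mask_policy == "near_black" else None
    if space == "lab":
        return channel_stats(rgb_to_lab(image), mask)
    if space == "rgb":
        # Same container; fields hold R, G, B statistics in this mode.
        return channel_stats(np.asarray(image, dtype=np.float64), mask)
    raise ValidationError(f"unknown transfer space {space!r}")


# A constant channel's computed SD is round-off, not signal; anything below
# this is treated as the sigma=0 degenerate case (lab values are O(1),
# 8-bit RGB values O(100), so 1e-8 is far below any real variation).
_DEGENERATE_SD = 1e-8


def stats_from_references(
    images: Sequence[np.ndarray],
    mask_policy: str = "none",
    space: str = "lab",
) -> ChannelStats:
    """Pool per-channel statistics over reference images.

    Combined as the pixel-count-weighted mean of means and root-mean-square
    of SDs, so a duplicated reference changes nothing.
    """
    if len(images) == 0:
        raise ValidationError("need at least one reference image")
    if mask_policy not in ("none", "near_black"):
        raise ValidationError(f"unknown mask_policy {mask_policy!r}")
    per = [_stats_of(img, space, mask_policy) for img in images]
    weights = np.array([s.n_pixels for s in per], dtype=np.float64)
    means = np.array([s.means for s in per])
    sds = np.array([s.sds for s in per])
    total = weights.sum()
    mean = (weights[:, None] * means).sum(axis=0) / total
    sd = np.sqrt((weights[:, None] * sds**2).sum(axis=0) / total)
    return ChannelStats.from_arrays(mean, sd, int(total))


def transfer_lab(source: np.ndarray, target: ChannelStats) -> np.ndarray:
    """Apply the moment match in lab space and return the raw lab result.

    This is the pre-clipping representation on which the moment-matching
    property holds exactly.
    """
    lab = rgb_to_lab(source)
    src = channel_stats(lab)
    out = np.empty_like(lab)
    for k in range(3):
        if src.sds[k] <= _DEGENERATE_SD:
            out[..., k] = target.means[k]
        else:
            scale = target.sds[k] / src.sds[k]
            out[..., k] = scale * (lab[..., k] - src.means[k]) + target.means[k]
    return out


def transfer(source: np.ndarray, target: ChannelStats, space: str = "lab") -> np.ndarray:
    """Color-transfer ``source`` toward ``target`` statistics; returns uint8 RGB."""
    if space == "lab":
        return lab_to_rgb(transfer_lab(source, target))
    if space == "rgb":
        arr = np.asarray(source, dtype=np.float64)
        src = channel_stats(arr)
        out = np.empty_like(arr)
        for k in range(3):
            if src.sds[k] <= _DEGENERATE_SD:
                out[..., k] = target.means[k]
            else:
                scale = target.sds[k] / src.sds[k]
                out[..., k] = scale * (arr[..., k] - src.means[k]) + target.means[k]
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    raise ValidationError(f"unknown transfer space {space!r}")


def transfer_dataset(
    manifest: DatasetManifest,
    src_root: str | Path,
    out_root: str | Path,
    style_stats: Mapping[str, ChannelStats | Sequence[ChannelStats]],
    *,
    space: str = "lab",
    seed: int = 0,
) -> DatasetManifest:
    """Transfer every source image once per requested style.

    ``style_stats`` maps a style id either to one pooled :class:`ChannelStats`
    (default policy) or to a list of per-reference stats, in which case
    references are assigned round-robin over the lexicographically ordered
    records (deterministic; ``seed`` reserved for future stochastic
    policies).  Output images land under ``out_root/<style>/<class>/...``;
    counts are conserved per class per style.
    """
    if len(manifest) == 0:
        raise ValidationError("manifest is empty")
    if not style_stats:
        raise ValidationError("at least one target style is required")
    src_root = Path(src_root)
    out_root = Path(out_root)
    records: list[ManifestRecord] = []
    ordered = sorted(manifest.records, key=lambda r: r.image_path)
    for style_id in sorted(style_stats):
        stats = style_stats[style_id]
        pooled = isinstance(stats, ChannelStats)
        for i, rec in enumerate(ordered):
            src_path = src_root / rec.image_path
            if not src_path.is_file():
                raise ValidationError(f"missing source file for record {rec.image_path!r}")
            image = load_image(src_path)
            tgt = stats if pooled else stats[i % len(stats)]
            result = transfer(image, tgt, space=space)
            rel = Path(style_id) / rec.image_path
            save_image(result, out_root / rel)
            records.append(
                replace(rec, image_path=rel.as_posix(), style_id=style_id)
            )
    records.sort(key=lambda r: r.image_path)
    return DatasetManifest(records=records, class_names=list(manifest.class_names))
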