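"""End-to-end dataset construction.

Stage order: source acquisition (scan a real tree or synthesise one) →
color transfer per target style → similarity gate → per-class balancing
augmentation (accepted records only; augmented variants inherit acceptance
from their source, being color-identical up to resampling) → optional
sharpen/detail filter stage → stratified 6:2:2 split.  The whole build is
deterministic under a fixed seed, and a JSON-able report captures
per-stage counts and per-class closest/farthest gate distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import synth as synthmod
from .augment import apply_transform, balance_class, chain_slug
from .embedding import embed
from .errors import CapacityError, ConfigError, ValidationError
from .filters import FILTER_NAMES, apply_filter
from .gate import GateConfig, gate
from .io import (
    DatasetManifest,
    ManifestRecord,
    load_image,
    save_image,
    scan_dataset,
    write_manifest,
)
from .transfer import stats_from_references, transfer_dataset


def split(
    manifest: DatasetManifest,
    ratio: tuple[int, int, int] = (6, 2, 2),
    seed: int = 0,
    group_by_source: bool = False,
) -> DatasetManifest:
    """Stratified train/val/test assignment.

    Per class, partition sizes are floor-allocated from the ratio with
    remainders handed out in ratio order (train, val, test).  With
    ``group_by_source`` every variant of one source image lands in a single
    partition, so sizes only approximate the ratio but no source leaks
    across partitions.
    """
    total = sum(ratio)
    if total <= 0 or min(ratio) < 0:
        raise ConfigError(f"split ratio must be nonnegative with positive sum, got {ratio}")
    parts = ("train", "val", "test")
    assigned: dict[str, str] = {}  # record image_path -> split
    for class_label, recs in manifest.by_class().items():
        recs = sorted(recs, key=lambda r: r.image_path)
        n = len(recs)
        base = [n * r // total for r in ratio]
        rem = n - sum(base)
        for i in range(rem):
            base[i % 3] += 1
        class_idx = manifest.class_names.index(class_label)
        rng = np.random.default_rng([seed, 7, class_idx])
        if not group_by_source:
            order = rng.permutation(n)
            bounds = np.cumsum(base)
            for rank, idx in enumerate(order):
                part = parts[int(np.searchsorted(bounds, rank, side="right"))]
                assigned[recs[idx].image_path] = part
        else:
            sources = sorted({r.source_id for r in recs})
            order = rng.permutation(len(sources))
            by_source: dict[str, list] = {}
            for r in recs:
                by_source.setdefault(r.source_id, []).append(r)
            filled = [0, 0, 0]
            for si in order:
                group = by_source[sources[si]]
                # put the whole group where the deficit is largest
                deficits = [base[j] - filled[j] for j in range(3)]
                j = int(np.argmax(deficits))
                filled[j] += len(group)
                for r in group:
                    assigned[r.image_path] = parts[j]
    records = [replace(r, split=assigned[r.image_path]) for r in manifest.records]
    return DatasetManifest(records=records, class_names=list(manifest.class_names))


@dataclass
class BuildConfig:
    """Everything the builder needs; loadable from YAML."""

    out_dir: str
    source_dir: str | None = None  # None -> synthesise the source tree
    reference_dirs: dict[str, str] | None = None  # style -> dir of reference images
    styles: tuple[str, ...] = ("L", "R", "G")
    n_references: int = 3
    per_class_counts: dict[str, int] | None = None  # synth counts; None -> default
    per_class_target: int = 1280
    split_ratio: tuple[int, int, int] = (6, 2, 2)
    group_split: bool = False
    gate_threshold: float = 1.0
    gate_tolerance: float = 0.2
    gate_reduce: str = "min"
    embed_method: str = "colorgrid"
    filter: str = "none"
    transfer_space: str = "lab"
    mask_policy: str = "none"  # reference-statistics mask: none | near_black
    image_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter not in FILTER_NAMES:
            raise ConfigError(f"unknown filter {self.filter!r}; known: {FILTER_NAMES}")
        if not self.styles:
            raise ConfigError("at least one target style is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BuildConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        for key in ("styles", "split_ratio"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def gate_config(self) -> GateConfig:
        return GateConfig(threshold=self.gate_threshold, tolerance_plus=self.gate_tolerance)


def build(config: BuildConfig) -> tuple[dict[str, DatasetManifest], dict]:
    """Run the full construction flow; returns per-style manifests + report."""
    out = Path(config.out_dir)
    synth_cfg = synthmod.SynthConfig(image_size=config.image_size)
    report: dict = {"stages": {}, "styles": {}}

    # --- stage 1: source images ------------------------------------------
    if config.source_dir is not None:
        source_root = Path(config.source_dir)
        source_manifest = scan_dataset(source_root)
    else:
        source_root = out / "source"
        source_manifest = synthmod.generate_dataset(
            config.per_class_counts, "wired", synth_cfg, config.seed, source_root
        )
    report["stages"]["source_images"] = len(source_manifest)

    # --- stage 2: style references + pooled statistics -------------------
    ref_images: dict[str, list[np.ndarray]] = {}
    if config.reference_dirs is not None:
        missing = [s for s in config.styles if s not in config.reference_dirs]
        if missing:
            raise ConfigError(f"styles {missing} have no reference_dirs entry")
        for style in config.styles:
            root = Path(config.reference_dirs[style])
            paths = sorted(
                p for p in root.rglob("*") if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
            )
            if not paths:
                raise ValidationError(f"no reference images under {root}")
            ref_images[style] = [load_image(p) for p in paths]
    else:
        ref_images = synthmod.generate_references(
            config.styles, config.n_references, synth_cfg, config.seed
        )
    style_stats = {
        style: stats_from_references(imgs, mask_policy=config.mask_policy,
                                     space=config.transfer_space)
        for style, imgs in ref_images.items()
    }
    ref_embeddings = {
        style: [embed(img, method=config.embed_method) for img in imgs]
        for style, imgs in ref_images.items()
    }

    # --- stage 3: color transfer -----------------------------------------
    transferred_root = out / "transferred"
    transferred = transfer_dataset(
        source_manifest, source_root, transferred_root, style_stats,
        space=config.transfer_space, seed=config.seed,
    )
    report["stages"]["transferred_images"] = len(transferred)

    # --- stage 4: similarity gate ----------------------------------------
    gated, sim_report = gate(
        transferred, transferred_root, ref_embeddings, config.gate_config,
        embed_method=config.embed_method, reduce=config.gate_reduce,
    )
    report["stages"]["gate"] = sim_report.to_dict()

    # --- stages 5-7 per style: balance, filter, split --------------------
    manifests: dict[str, DatasetManifest] = {}
    accepted_by_style: dict[str, list[ManifestRecord]] = {s: [] for s in config.styles}
    for rec, ok in zip(gated.records, sim_report.accepted):
        if ok:
            accepted_by_style[rec.style_id].append(rec)
    per_class_dist: dict[str, dict[str, dict[str, float]]] = {s: {} for s in config.styles}
    for rec in gated.records:
        d = per_class_dist[rec.style_id].setdefault(
            rec.class_label, {"closest": rec.gate_distance, "farthest": rec.gate_distance}
        )
        d["closest"] = min(d["closest"], rec.gate_distance)
        d["farthest"] = max(d["farthest"], rec.gate_distance)

    for style_idx, style in enumerate(config.styles):
        accepted = accepted_by_style[style]
        if not accepted:
            raise CapacityError(f"gate accepted no images for style {style!r}")
        dataset_root = out / "dataset" / style
        final_records: list[ManifestRecord] = []
        by_class: dict[str, list[ManifestRecord]] = {}
        for rec in accepted:
            by_class.setdefault(rec.class_label, []).append(rec)
        for cls in sorted(by_class):
            cls_idx = source_manifest.class_names.index(cls)
            plan = balance_class(
                by_class[cls],
                config.per_class_target,
                seed=int(np.random.default_rng([config.seed, 3, style_idx, cls_idx]).integers(2**31)),
            )
            for rec, chain in plan:
                image = apply_transform(load_image(transferred_root / rec.image_path), chain)
                chain_out = chain
                if config.filter != "none":
                    image = apply_filter(image, config.filter)
                    chain_out = chain + (config.filter,)
                stem = Path(rec.image_path).name.rsplit(".", 1)[0]
                rel = Path(cls) / f"{stem}__{chain_slug(chain_out)}.png"
                save_image(image, dataset_root / rel)
                final_records.append(
                    replace(
                        rec,
                        image_path=rel.as_posix(),
                        transform_chain=chain_out,
                    )
                )
        final_records.sort(key=lambda r: r.image_path)
        final = DatasetManifest(records=final_records, class_names=list(source_manifest.class_names))
        final = split(
            final, config.split_ratio, seed=config.seed, group_by_source=config.group_split
        )
        write_manifest(final, dataset_root / "manifest.csv")
        manifests[style] = final
        counts = final.counts()
        split_totals = {"train": 0, "val": 0, "test": 0}
        for cls_counts in counts.values():
            for part, c in cls_counts.items():
                split_totals[part] += c
        report["styles"][style] = {
            "accepted": len(accepted),
            "rejected": sum(
                1 for r, ok in zip(gated.records, sim_report.accepted)
                if r.style_id == style and not ok
            ),
            "balanced_total": len(final),
            "per_class_distance": per_class_dist[style],
            "split_totals": split_totals,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return manifests, report
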