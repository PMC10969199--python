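"""Image and manifest I/O.

Images are plain ``uint8`` RGB arrays of shape ``(H, W, 3)``.  A dataset is a
directory tree with one subdirectory per class; its tabular description is a
:class:`DatasetManifest`, serialised as a header-bearing CSV whose
``transform_chain`` column is JSON-encoded.  Paths inside a manifest are
always relative (POSIX separators) so datasets are relocatable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import DecodeError, ManifestParseError, ValidationError

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

SPLITS = ("train", "val", "test", "unassigned")

_MANIFEST_COLUMNS = [
    "image_path",
    "class_label",
    "source_id",
    "transform_chain",
    "style_id",
    "gate_distance",
    "split",
]


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check that ``image`` is a valid 8-bit RGB array and return it.

    Filter kernels and the colorgrid embedder need at least a 3x3 canvas.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValidationError(f"image too small ({arr.shape[0]}x{arr.shape[1]}); need >= 3x3")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValidationError(f"expected uint8 intensities in [0,255], got dtype {arr.dtype}")
    return arr


def load_image(path: str | Path) -> np.ndarray:
    """Decode a PNG/JPEG file to a uint8 RGB array.

    Grayscale images are replicated to three channels; an alpha channel is
    dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    return validate_rgb(arr)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a uint8 RGB array as PNG (or JPEG, by suffix). PNG is lossless."""
    arr = validate_rgb(image)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="RGB").save(path)


@dataclass
class ManifestRecord:
    """One image's identity and provenance.

    ``source_id`` names the originating un-augmented image;
    ``transform_chain`` lists the geometric/filter transforms applied, in
    order; ``style_id`` is the color-transfer target style ("original" if
    untransferred); ``gate_distance`` is the embedding-space Euclidean
    distance to the style references once gated.
    """

    image_path: str
    class_label: str
    source_id: str
    transform_chain: tuple[str, ...] = ()
    style_id: str = "original"
    gate_distance: float | None = None
    split: str = "unassigned"

    def __post_init__(self) -> None:
        self.transform_chain = tuple(self.transform_chain)
        if self.split not in SPLITS:
            raise ValidationError(f"unknown split {self.split!r}")
        if self.gate_distance is not None and self.gate_distance < 0:
            raise ValidationError("gate_distance must be nonnegative")

    @property
    def key(self) -> tuple[str, tuple[str, ...], str]:
        return (self.source_id, self.transform_chain, self.style_id)


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.class_names)
        for rec in self.records:
            if rec.class_label not in known:
                raise ValidationError(
                    f"record {rec.image_path!r} has class {rec.class_label!r} "
                    f"not in class_names {self.class_names}"
                )
        keys = [rec.key for rec in self.records]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValidationError(f"duplicate (source_id, chain, style) key {k}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.records)

    def by_class(self) -> dict[str, list[ManifestRecord]]:
        out: dict[str, list[ManifestRecord]] = {c: [] for c in self.class_names}
        for rec in self.records:
            out[rec.class_label].append(rec)
        return out

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-class record counts, split out by partition."""
        out: dict[str, dict[str, int]] = {}
        for rec in self.records:
            cls = out.setdefault(rec.class_label, {})
            cls[rec.split] = cls.get(rec.split, 0) + 1
        return out

    def subset(self, indices: Iterable[int]) -> "DatasetManifest":
        recs = [replace(self.records[i]) for i in indices]
        return DatasetManifest(records=recs, class_names=list(self.class_names))


def scan_dataset(root_dir: str | Path) -> DatasetManifest:
    """Build a manifest from a class-per-subdirectory image tree.

    Ordering is lexicographic by relative path, so two scans of the same
    tree produce identical manifests regardless of filesystem order.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise ValidationError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValidationError(f"dataset root {root} contains no class subdirectories")
    records: list[ManifestRecord] = []
    class_names: list[str] = []
    for cdir in class_dirs:
        files = sorted(
            p for p in cdir.rglob("*") if p.is_file() and p.suffix.lower() in IMAGE_SUFFIXES
        )
        if not files:
            raise ValidationError(f"class directory {cdir.name!r} contains no images")
        class_names.append(cdir.name)
        for f in files:
            rel = f.relative_to(root).as_posix()
            records.append(
                ManifestRecord(
                    image_path=rel,
                    class_label=cdir.name,
                    source_id=rel.rsplit(".", 1)[0],
                )
            )
    records.sort(key=lambda r: r.image_path)
    return DatasetManifest(records=records, class_names=class_names)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Serialise a manifest as CSV; first line carries the class list."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in manifest.records:
        rows.append(
            {
                "image_path": rec.image_path,
                "class_label": rec.class_label,
                "source_id": rec.source_id,
                "transform_chain": json.dumps(list(rec.transform_chain)),
                "style_id": rec.style_id,
                "gate_distance": "" if rec.gate_distance is None else repr(float(rec.gate_distance)),
                "split": rec.split,
            }
        )
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    header = "# class_names: " + json.dumps(manifest.class_names) + "\n"
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# class_names:"):
            raise ManifestParseError(f"{path}:1: missing '# class_names:' header line")
        try:
            class_names = json.loads(first.split(":", 1)[1])
        except json.JSONDecodeError as exc:
            raise ManifestParseError(f"{path}:1: bad class_names JSON: {exc}") from exc
        try:
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
        except Exception as exc:  # pandas raises several parser error types
            raise ManifestParseError(f"{path}: CSV parse failure: {exc}") from exc
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestParseError(f"{path}:2: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=3):
        try:
            chain = tuple(json.loads(row.transform_chain))
        except json.JSONDecodeError as exc:
            raise ManifestParseError(f"{path}:{i}: bad transform_chain JSON: {exc}") from exc
        gate = None if row.gate_distance == "" else float(row.gate_distance)
        records.append(
            ManifestRecord(
                image_path=row.image_path,
                class_label=row.class_label,
                source_id=row.source_id,
                transform_chain=chain,
                style_id=row.style_id,
                gate_distance=gate,
                split=row.split,
            )
        )
    return DatasetManifest(records=records, class_names=list(class_names))
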