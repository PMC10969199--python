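"""Similarity measurement and the acceptance gate.

A color-transferred image is accepted when its embedding-space Euclidean
distance to its style's reference images is at most ``threshold +
tolerance_plus`` (default 1.0 + 0.2 = 1.2).  Only the upper side of the
band matters: a small distance means high similarity, so distances below
threshold - tolerance always pass.

A record's distance to "the target" is the minimum over the style's
reference embeddings (conservative; a ``reduce="mean"`` mode averages
instead).  Rejected records are never deleted — they are reported with
``accepted=False`` so downstream stages can filter while the full audit
trail survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .embedding import Embedding, embed
from .errors import ConfigError, ValidationError
from .io import DatasetManifest, load_image


@dataclass(frozen=True)
class GateConfig:
    """Acceptance band for the similarity gate."""

    threshold: float = 1.0
    tolerance_plus: float = 0.2

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if self.tolerance_plus < 0:
            raise ValidationError("tolerance_plus must be nonnegative")

    @property
    def max_distance(self) -> float:
        return self.threshold + self.tolerance_plus


@dataclass
class SimilarityReport:
    """Per-record distances plus per-class closest/farthest summary."""

    distances: list[float]
    accepted: list[bool]
    per_class_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return sum(self.accepted)

    @property
    def n_rejected(self) -> int:
        return len(self.accepted) - self.n_accepted

    def to_dict(self) -> dict:
        return {
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "per_class_range": {
                c: {"closest": lo, "farthest": hi}
                for c, (lo, hi) in sorted(self.per_class_range.items())
            },
        }


def _check_pair(p: Embedding, q: Embedding) -> None:
    if p.method_id != q.method_id:
        raise ValidationError(
            f"embedding methods differ: {p.method_id!r} vs {q.method_id!r}"
        )
    if p.dim != q.dim:
        raise ValidationError(f"embedding dimensions differ: {p.dim} vs {q.dim}")


def euclidean_distance(p: Embedding, q: Embedding) -> float:
    """``||p - q||_2``; symmetric, zero iff the vectors coincide."""
    _check_pair(p, q)
    return float(np.linalg.norm(p.values - q.values))


def cosine_similarity(a: Embedding, b: Embedding) -> float:
    """``a.b / (||a|| ||b||)``, in [-1, 1]."""
    _check_pair(a, b)
    na = np.linalg.norm(a.values)
    nb = np.linalg.norm(b.values)
    if na == 0.0 or nb == 0.0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(np.dot(a.values, b.values) / (na * nb))


def distance_to_references(
    emb: Embedding, references: Sequence[Embedding], reduce: str = "min"
) -> float:
    if len(references) == 0:
        raise ValidationError("need at least one reference embedding")
    ds = [euclidean_distance(emb, r) for r in references]
    if reduce == "min":
        return min(ds)
    if reduce == "mean":
        return float(np.mean(ds))
    raise ConfigError(f"unknown reduce {reduce!r}; known: min, mean")


def gate(
    manifest: DatasetManifest,
    images_root: str | Path,
    reference_embeddings: Mapping[str, Sequence[Embedding]],
    config: GateConfig = GateConfig(),
    *,
    embed_method: str = "colorgrid",
    reduce: str = "min",
) -> tuple[DatasetManifest, SimilarityReport]:
    """Gate every record against its style's references.

    Returns a manifest copy with ``gate_distance`` filled in, plus the
    report.  Records keep their manifest order; acceptance flags align with
    it.
    """
    images_root = Path(images_root)
    distances: list[float] = []
    accepted: list[bool] = []
    new_records = []
    per_class: dict[str, list[float]] = {}
    for rec in manifest.records:
        if rec.style_id not in reference_embeddings:
            raise ValidationError(
                f"record {rec.image_path!r} has style {rec.style_id!r} with no references"
            )
        refs = reference_embeddings[rec.style_id]
        emb = embed(load_image(images_root / rec.image_path), method=embed_method)
        d = distance_to_references(emb, refs, reduce=reduce)
        distances.append(d)
        accepted.append(d <= config.max_distance)
        per_class.setdefault(rec.class_label, []).append(d)
        new_records.append(replace(rec, gate_distance=d))
    report = SimilarityReport(
        distances=distances,
        accepted=accepted,
        per_class_range={c: (min(v), max(v)) for c, v in per_class.items()},
    )
    gated = DatasetManifest(records=new_records, class_names=list(manifest.class_names))
    return gated, report
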