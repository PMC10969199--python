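"""Seeded synthetic endoscopy-like image generator.

Every pipeline stage is testable without downloads: this module fabricates
wired-endoscopy-style and capsule-style frames with (a) class structure —
each of the five gastric landmark classes gets an oriented sinusoidal
"fold" motif with its own orientation, spatial frequency and amplitude —
and (b) style structure — each style imposes its own l-alpha-beta channel
means/SDs, with the wired style noticeably brighter (higher l) and pinker
than the darker, warmer capsule styles "L", "R" and "G".

Frames are drawn directly in lab space (motif + Gaussian noise), converted
to RGB, and masked with a circular black vignette like real endoscopy
frames.  The motifs are abstract folds, not anatomy: the goal is
statistical separability of classes and styles, not visual realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .colorspace import lab_to_rgb
from .errors import ValidationError
from .io import DatasetManifest, ManifestRecord, save_image

#: Class counts of the motivating five-landmark gastric dataset.
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "Angulus": 493,
    "Antrum": 901,
    "Body A": 533,
    "Body B": 392,
    "Cardia and Fundus": 207,
}


@dataclass(frozen=True)
class ClassSpec:
    """Fold-texture motif of one landmark class."""

    orientation_deg: float
    frequency: float  # cycles across the frame
    amplitude: float  # texture amplitude in lab l units


@dataclass(frozen=True)
class StyleSpec:
    """Target lab channel statistics of one imaging style."""

    mean: tuple[float, float, float]  # (l, alpha, beta)
    sd: tuple[float, float, float]


DEFAULT_CLASS_SPECS: dict[str, ClassSpec] = {
    "Angulus": ClassSpec(0.0, 4.0, 0.28),
    "Antrum": ClassSpec(36.0, 6.0, 0.22),
    "Body A": ClassSpec(72.0, 8.0, 0.32),
    "Body B": ClassSpec(108.0, 5.0, 0.24),
    "Cardia and Fundus": ClassSpec(144.0, 7.0, 0.30),
}

# Wired frames are bright and pink; capsule frames darker and warmer, with
# per-style chromatic offsets so the three capsule variants are separable.
DEFAULT_STYLE_SPECS: dict[str, StyleSpec] = {
    "wired": StyleSpec(mean=(-0.50, 0.08, 0.033), sd=(0.30, 0.030, 0.020)),
    "L": StyleSpec(mean=(-0.90, 0.17, 0.050), sd=(0.22, 0.040, 0.030)),
    "R": StyleSpec(mean=(-0.85, 0.12, 0.090), sd=(0.22, 0.050, 0.020)),
    "G": StyleSpec(mean=(-1.00, 0.20, 0.020), sd=(0.26, 0.030, 0.040)),
}


@dataclass
class SynthConfig:
    class_specs: dict[str, ClassSpec] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECS)
    )
    style_specs: dict[str, StyleSpec] = field(
        default_factory=lambda: dict(DEFAULT_STYLE_SPECS)
    )
    image_size: int = 256
    vignette_fraction: float = 0.95  # circle radius as a fraction of the half-size
    noise_sd: float = 0.05  # lab-space pixel noise

    def __post_init__(self) -> None:
        if not self.class_specs or not self.style_specs:
            raise ValidationError("need at least one class and one style")
        for name, spec in self.style_specs.items():
            if min(spec.sd) <= 0:
                raise ValidationError(f"style {name!r} has a nonpositive SD")
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")

    def class_index(self, class_id: str) -> int:
        try:
            return sorted(self.class_specs).index(class_id)
        except ValueError:
            raise ValidationError(f"unknown class {class_id!r}") from None

    def style_index(self, style_id: str) -> int:
        try:
            return sorted(self.style_specs).index(style_id)
        except ValueError:
            raise ValidationError(f"unknown style {style_id!r}") from None


def generate_image(
    class_id: str,
    style_id: str,
    config: SynthConfig = SynthConfig(),
    seed: int = 0,
    index: int = 0,
) -> np.ndarray:
    """Render one frame, deterministically in (class, style, seed, index).

    The fold texture modulates all three lab channels (dominantly l) so the
    class signal survives color transfer; channel offsets and spreads come
    from the style spec.
    """
    cspec = config.class_specs.get(class_id)
    sspec = config.style_specs.get(style_id)
    if cspec is None:
        raise ValidationError(f"unknown class {class_id!r}")
    if sspec is None:
        raise ValidationError(f"unknown style {style_id!r}")
    rng = np.random.default_rng(
        [seed, config.class_index(class_id), config.style_index(style_id), index]
    )
    n = config.image_size
    coords = np.linspace(-1.0, 1.0, n)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    theta = np.deg2rad(cspec.orientation_deg)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    arg = np.pi * cspec.frequency * (xx * np.cos(theta) + yy * np.sin(theta)) + phase
    fold = np.sin(arg)
    # Secondary harmonic gives the folds some thickness variation.
    fold = 0.8 * fold + 0.2 * np.sin(2.0 * arg + rng.uniform(0.0, 2.0 * np.pi))
    fold /= fold.std() or 1.0

    lab = np.empty((n, n, 3))
    mean, sd = np.array(sspec.mean), np.array(sspec.sd)
    texture_share = (0.9, 0.5, 0.5)  # fraction of each channel's SD carried by the motif
    for k in range(3):
        t = texture_share[k] * (cspec.amplitude / 0.3)
        t = min(t, 0.98)
        structured = sd[k] * t * fold
        # Independent noise fills out the remaining channel variance, so the
        # realised SD approximates the style spec regardless of motif share.
        noise = rng.normal(0.0, sd[k] * np.sqrt(1.0 - t**2), lab.shape[:2])
        lab[..., k] = mean[k] + structured + noise
    # Additive sensor-like noise on the achromatic channel.
    lab[..., 0] += rng.normal(0.0, config.noise_sd, lab.shape[:2])
    rgb = lab_to_rgb(lab)
    r = np.sqrt(xx**2 + yy**2)
    rgb[r > config.vignette_fraction] = 0
    return rgb


def generate_dataset(
    per_class_counts: Mapping[str, int] | None,
    style_id: str,
    config: SynthConfig,
    seed: int,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write a class-per-subdirectory tree of synthetic frames.

    ``per_class_counts`` defaults to the five-landmark distribution
    (493/901/533/392/207, total 2526).  Images and manifest ordering are
    fully determined by ``seed``.
    """
    if per_class_counts is None:
        per_class_counts = DEFAULT_CLASS_COUNTS
    out = Path(out_dir)
    records: list[ManifestRecord] = []
    class_names = sorted(per_class_counts)
    for class_id in class_names:
        count = per_class_counts[class_id]
        if count < 1:
            raise ValidationError(f"class {class_id!r} needs a count >= 1, got {count}")
        slug = class_id.replace(" ", "_")
        for i in range(count):
            img = generate_image(class_id, style_id, config, seed=seed, index=i)
            rel = Path(class_id) / f"{slug}_{i:04d}.png"
            save_image(img, out / rel)
            records.append(
                ManifestRecord(
                    image_path=rel.as_posix(),
                    class_label=class_id,
                    source_id=rel.as_posix().rsplit(".", 1)[0],
                    style_id="original" if style_id == "wired" else style_id,
                )
            )
    records.sort(key=lambda r: r.image_path)
    return DatasetManifest(records=records, class_names=class_names)


def generate_references(
    style_ids: Sequence[str],
    n_per_style: int,
    config: SynthConfig,
    seed: int,
) -> dict[str, list[np.ndarray]]:
    """In-memory capsule-style reference frames, one list per style.

    References cycle through the classes so pooled statistics are not
    dominated by a single motif.
    """
    classes = sorted(config.class_specs)
    out: dict[str, list[np.ndarray]] = {}
    for style in style_ids:
        imgs = []
        for j in range(n_per_style):
            cls = classes[j % len(classes)]
            imgs.append(generate_image(cls, style, config, seed=seed, index=10_000 + j))
        out[style] = imgs
    return out
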