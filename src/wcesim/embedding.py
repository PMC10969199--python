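"""Image embeddings for similarity measurement.

Distances between images are measured between fixed-length unit-norm
vectors.  The built-in ``colorgrid`` method is deterministic and
weight-free: the image is resized to 32x32 (bilinear), converted to
l-alpha-beta, and per-channel mean and SD are taken over a 4x4 spatial
grid, giving 4*4*3*2 = 96 features, then L2-normalised.

A ``cnn`` slot accepts a user-registered backend (e.g. a pretrained VGG16
penultimate layer) whose raw feature vector is L2-normalised the same way;
nothing is ever downloaded implicitly.

L2 normalisation bounds every pairwise Euclidean distance to [0, 2], which
is what makes a fixed acceptance threshold like 1.2 meaningful across
embedding methods.  This is the single most consequential convention in the
package and is relied on by the similarity gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.transform import resize

from .colorspace import rgb_to_lab
from .errors import ConfigError, ValidationError

COLORGRID_SIZE = 32
COLORGRID_CELLS = 4


@dataclass(frozen=True)
class Embedding:
    """A unit-norm feature vector tagged with the method that produced it."""

    values: np.ndarray
    method_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValidationError("embedding values must be a 1-D vector")
        if not np.isfinite(v).all():
            raise ValidationError("embedding contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return int(self.values.shape[0])


def _normalize(values: np.ndarray, method_id: str) -> Embedding:
    v = np.asarray(values, dtype=np.float64).ravel()
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValidationError("cannot normalise an all-zero feature vector")
    return Embedding(values=v / norm, method_id=method_id)


def colorgrid_features(image: np.ndarray) -> np.ndarray:
    """Raw (un-normalised) colorgrid features of an RGB image."""
    arr = np.asarray(image, dtype=np.float64)
    small = resize(
        arr,
        (COLORGRID_SIZE, COLORGRID_SIZE, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    lab = rgb_to_lab(small)
    c = COLORGRID_CELLS
    s = COLORGRID_SIZE // c
    cells = lab.reshape(c, s, c, s, 3)
    means = cells.mean(axis=(1, 3))  # (4, 4, 3)
    sds = cells.std(axis=(1, 3), ddof=0)
    return np.concatenate([means.ravel(), sds.ravel()])


_cnn_backend: Callable[[np.ndarray], np.ndarray] | None = None


def register_cnn_backend(fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a feature extractor for the ``cnn`` method.

    ``fn`` maps a uint8 RGB array to a 1-D feature vector (e.g. the
    penultimate-layer activations of an ImageNet-pretrained VGG16).
    """
    global _cnn_backend
    _cnn_backend = fn


def clear_cnn_backend() -> None:
    global _cnn_backend
    _cnn_backend = None


def embed(image: np.ndarray, method: str = "colorgrid") -> Embedding:
    """Embed an image with the named method; result is unit-norm."""
    if method == "colorgrid":
        return _normalize(colorgrid_features(image), "colorgrid")
    if method == "cnn":
        if _cnn_backend is None:
            raise ConfigError(
                "method 'cnn' requires a registered backend; call "
                "register_cnn_backend() with a feature extractor first "
                "(no model is ever downloaded implicitly)"
            )
        return _normalize(_cnn_backend(np.asarray(image)), "cnn")
    raise ConfigError(f"unknown embedding method {method!r}; known: colorgrid, cnn")
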