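import numpy as np
import pytest

from wcesim.embedding import Embedding, embed
from wcesim.errors import ValidationError
from wcesim.gate import (
    GateConfig,
    cosine_similarity,
    distance_to_references,
    euclidean_distance,
    gate,
)
from wcesim.io import DatasetManifest, ManifestRecord, save_image


def unit(v):
    v = np.asarray(v, dtype=float)
    return Embedding(values=v / np.linalg.norm(v), method_id="test")


class TestDistanceIdentities:
    def test_self_distance_zero(self, rng):
        x = unit(rng.normal(size=16))
        assert euclidean_distance(x, x) == 0.0

    def test_orthonormal_pair_sqrt2(self):
        e1 = unit([1, 0, 0])
        e2 = unit([0, 1, 0])
        assert abs(euclidean_distance(e1, e2) - np.sqrt(2)) < 1e-12

    def test_squared_distance_equals_two_minus_two_cos(self, rng):
        for _ in range(25):
            p, q = unit(rng.normal(size=32)), unit(rng.normal(size=32))
            d2 = euclidean_distance(p, q) ** 2
            assert abs(d2 - 2 * (1 - cosine_similarity(p, q))) < 1e-9

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = (unit(rng.normal(size=8)) for _ in range(3))
            assert abs(euclidean_distance(a, b) - euclidean_distance(b, a)) < 1e-12
            assert euclidean_distance(a, c) <= (
                euclidean_distance(a, b) + euclidean_distance(b, c) + 1e-12
            )

    def test_unit_norm_bounds_distance_to_two(self, rng):
        for _ in range(20):
            p, q = unit(rng.normal(size=8)), unit(rng.normal(size=8))
            assert 0.0 <= euclidean_distance(p, q) <= 2.0 + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            euclidean_distance(unit([1, 0]), unit([1, 0, 0]))

    def test_method_mismatch_rejected(self):
        a = Embedding(values=np.array([1.0, 0.0]), method_id="a")
        b = Embedding(values=np.array([1.0, 0.0]), method_id="b")
        with pytest.raises(ValidationError):
            euclidean_distance(a, b)


class TestCosine:
    def test_self_similarity_one(self, rng):
        x = unit(rng.normal(size=8))
        assert abs(cosine_similarity(x, x) - 1.0) < 1e-12

    def test_orthogonal_zero(self):
        assert abs(cosine_similarity(unit([1, 0]), unit([0, 1]))) < 1e-12

    def test_matches_brute_force(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        ea, eb = unit(a), unit(b)
        dot = sum(x * y for x, y in zip(ea.values, eb.values))
        na = sum(x * x for x in ea.values) ** 0.5
        nb = sum(x * x for x in eb.values) ** 0.5
        assert abs(cosine_similarity(ea, eb) - dot / (na * nb)) < 1e-12


class TestGateConfig:
    def test_default_band_is_one_plus_point_two(self):
        cfg = GateConfig()
        assert cfg.threshold == 1.0
        assert cfg.max_distance == pytest.approx(1.2)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValidationError):
            GateConfig(threshold=0.0)
        with pytest.raises(ValidationError):
            GateConfig(tolerance_plus=-0.1)


class _GateFixture:
    """20 random images across 2 classes, one style, on-disk, with refs."""

    def __init__(self, tmp_path, rng):
        self.root = tmp_path / "imgs"
        records = []
        for i in range(20):
            cls = "a" if i < 11 else "b"
            img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
            rel = f"{cls}/img_{i:02d}.png"
            save_image(img, self.root / rel)
            records.append(ManifestRecord(rel, cls, rel[:-4], style_id="G"))
        self.manifest = DatasetManifest(records=records, class_names=["a", "b"])
        self.refs = [
            embed(rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8))
            for _ in range(3)
        ]


class TestGateOperation:
    def test_threshold_band_accepts_correctly(self):
        # distances {0.9, 1.1, 1.3} against max 1.2 -> yes, yes, no
        cfg = GateConfig(threshold=1.0, tolerance_plus=0.2)
        assert [d <= cfg.max_distance for d in (0.9, 1.1, 1.3)] == [True, True, False]

    def test_small_distances_always_pass(self):
        # the lower (-0.2) side is excluded: near-zero distance passes
        cfg = GateConfig()
        assert 0.01 <= cfg.max_distance

    def test_per_class_minmax_match_exhaustive(self, tmp_path, rng):
        fx = _GateFixture(tmp_path, rng)
        gated, report = gate(fx.manifest, fx.root, {"G": fx.refs})
        # exhaustive oracle over all record-reference pairs
        from wcesim.io import load_image

        for cls in ("a", "b"):
            dists = []
            for rec in fx.manifest.records:
                if rec.class_label != cls:
                    continue
                e = embed(load_image(fx.root / rec.image_path))
                dists.append(min(euclidean_distance(e, r) for r in fx.refs))
            lo, hi = report.per_class_range[cls]
            assert lo == pytest.approx(min(dists), abs=1e-12)
            assert hi == pytest.approx(max(dists), abs=1e-12)

    def test_monotone_in_max_distance(self, tmp_path, rng):
        fx = _GateFixture(tmp_path, rng)
        counts = []
        for tol in (0.0, 0.1, 0.3, 0.7, 1.0):
            _, report = gate(
                fx.manifest, fx.root, {"G": fx.refs},
                GateConfig(threshold=0.2, tolerance_plus=tol),
            )
            counts.append(report.n_accepted)
        assert counts == sorted(counts)
        assert all(
            a + r == 20 for a, r in
            [(report.n_accepted, report.n_rejected)]
        )

    def test_zero_max_only_identical_accepted(self, tmp_path, rng):
        fx = _GateFixture(tmp_path, rng)
        refs = {"G": [embed(np.zeros((16, 16, 3), np.uint8))]}
        _, report = gate(fx.manifest, fx.root, refs,
                         GateConfig(threshold=1e-12, tolerance_plus=0.0))
        assert report.n_accepted == 0  # no record equals the reference

    def test_unknown_style_named(self, tmp_path, rng):
        fx = _GateFixture(tmp_path, rng)
        with pytest.raises(ValidationError, match="G"):
            gate(fx.manifest, fx.root, {"L": fx.refs})

    def test_gate_distance_written_back(self, tmp_path, rng):
        fx = _GateFixture(tmp_path, rng)
        gated, report = gate(fx.manifest, fx.root, {"G": fx.refs})
        assert all(r.gate_distance is not None for r in gated.records)
        assert [r.gate_distance for r in gated.records] == report.distances

    def test_mean_reduce_mode(self, rng):
        e = unit(rng.normal(size=8))
        refs = [unit(rng.normal(size=8)) for _ in range(3)]
        dmin = distance_to_references(e, refs, reduce="min")
        dmean = distance_to_references(e, refs, reduce="mean")
        assert dmin <= dmean
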