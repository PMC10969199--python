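import numpy as np
import pytest

from wcesim.colorspace import ChannelStats, channel_stats, rgb_to_lab
from wcesim.errors import ValidationError
from wcesim.io import write_manifest
from wcesim.transfer import (
    stats_from_references,
    transfer,
    transfer_dataset,
    transfer_lab,
)

TARGET = ChannelStats(-0.9, 0.17, 0.05, 0.22, 0.04, 0.03, 1000)


class TestTransfer:
    def test_moment_matching_pre_clipping(self, random_image):
        out_lab = transfer_lab(random_image, TARGET)
        s = channel_stats(out_lab)
        np.testing.assert_allclose(s.means, TARGET.means, rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(s.sds, TARGET.sds, rtol=1e-6, atol=1e-9)

    def test_self_transfer_is_identity(self, random_image):
        own = channel_stats(rgb_to_lab(random_image))
        out = transfer(random_image, own)
        assert np.abs(out.astype(int) - random_image.astype(int)).max() <= 1

    def test_constant_source_maps_to_target_mean(self):
        const = np.full((8, 8, 3), 77, np.uint8)
        out = transfer(const, TARGET)
        # sigma_source = 0 per channel -> constant at the target mean color
        assert (out == out[0, 0]).all()
        s = channel_stats(rgb_to_lab(out))
        np.testing.assert_allclose(s.means, TARGET.means, atol=0.02)

    def test_monotone_ordering_preserved(self, random_image):
        lab = rgb_to_lab(random_image)
        out = transfer_lab(random_image, TARGET)
        for k in range(3):
            order_in = np.argsort(lab[..., k].ravel(), kind="stable")
            order_out = np.argsort(out[..., k].ravel(), kind="stable")
            assert (order_in == order_out).all()

    def test_rgb_space_mode_matches_moments(self, random_image):
        tgt = ChannelStats(120.0, 80.0, 60.0, 30.0, 20.0, 10.0, 1000)
        out = transfer(random_image, tgt, space="rgb")
        s = channel_stats(out.astype(np.float64))
        np.testing.assert_allclose(s.means, tgt.means, atol=1.0)


class TestStatsFromReferences:
    def test_single_reference_matches_channel_stats(self, random_image):
        pooled = stats_from_references([random_image])
        direct = channel_stats(rgb_to_lab(random_image))
        np.testing.assert_allclose(pooled.means, direct.means, atol=1e-12)
        np.testing.assert_allclose(pooled.sds, direct.sds, atol=1e-12)

    def test_duplicated_reference_is_idempotent(self, random_image):
        one = stats_from_references([random_image])
        two = stats_from_references([random_image, random_image])
        np.testing.assert_allclose(one.means, two.means, atol=1e-12)
        np.testing.assert_allclose(one.sds, two.sds, atol=1e-12)

    def test_matches_brute_force_combination(self, rng):
        imgs = [rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8)
                for h, w in [(8, 8), (12, 6)]]
        pooled = stats_from_references(imgs)
        per = [channel_stats(rgb_to_lab(i)) for i in imgs]
        n = np.array([s.n_pixels for s in per], dtype=float)
        mean = sum(ni * s.means for ni, s in zip(n, per)) / n.sum()
        sd = np.sqrt(sum(ni * s.sds**2 for ni, s in zip(n, per)) / n.sum())
        np.testing.assert_allclose(pooled.means, mean, atol=1e-9)
        np.testing.assert_allclose(pooled.sds, sd, atol=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            stats_from_references([])


class TestTransferDataset:
    def test_counts_conserved_per_style(self, small_tree, tmp_path):
        from wcesim.io import scan_dataset

        root, counts = small_tree
        manifest = scan_dataset(root)
        styles = {"L": TARGET, "R": TARGET, "G": TARGET}
        out = transfer_dataset(manifest, root, tmp_path / "out", styles)
        assert len(out) == 3 * sum(counts.values())
        per = {}
        for rec in out.records:
            per[(rec.style_id, rec.class_label)] = per.get((rec.style_id, rec.class_label), 0) + 1
        for s in styles:
            for c, n in counts.items():
                assert per[(s, c)] == n

    def test_zero_styles_rejected(self, small_tree, tmp_path):
        from wcesim.io import scan_dataset

        root, _ = small_tree
        with pytest.raises(ValidationError):
            transfer_dataset(scan_dataset(root), root, tmp_path / "o", {})

    def test_missing_source_named_in_error(self, small_tree, tmp_path):
        from wcesim.io import scan_dataset

        root, _ = small_tree
        manifest = scan_dataset(root)
        (root / manifest.records[0].image_path).unlink()
        with pytest.raises(ValidationError, match=manifest.records[0].image_path):
            transfer_dataset(manifest, root, tmp_path / "o", {"G": TARGET})

    def test_same_seed_byte_identical_manifests(self, small_tree, tmp_path):
        from wcesim.io import scan_dataset

        root, _ = small_tree
        manifest = scan_dataset(root)
        for tag in ("a", "b"):
            out = transfer_dataset(manifest, root, tmp_path / tag, {"G": TARGET}, seed=5)
            write_manifest(out, tmp_path / f"{tag}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
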