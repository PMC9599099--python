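"""The truncation attack: identity limits, monotone degradation, batches."""

from pathlib import Path

import numpy as np
import pytest

from mbada import (
    AttackConfig,
    FixtureSpec,
    IntensityImage,
    attack_batch,
    attack_image,
    generate,
    mean_ssim,
)


class TestAttackImage:
    def test_full_order_is_identity(self, rng):
        img = IntensityImage(rng.random((32, 32)))
        res = attack_image(img, AttackConfig(order=31, output_encoding="float"))
        assert np.abs(res.adversarial.pixels - img.pixels).max() <= 1e-6
        assert res.ssim_vs_original >= 0.9999
        assert res.order_used == 31

    def test_constant_image_order_zero_unchanged(self):
        img = generate(FixtureSpec(kind="constant", height=20, width=20, value=0.5))
        res = attack_image(img, AttackConfig(order=0, output_encoding="float"))
        assert np.abs(res.adversarial.pixels - img.pixels).max() <= 1e-12
        assert res.clipped_fraction == 0.0

    def test_ssim_non_increasing_in_truncation(self, nuclei_pair):
        img, _ = nuclei_pair
        ssims = [
            attack_image(img, AttackConfig(order=k)).ssim_vs_original
            for k in (60, 40, 20, 10)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(ssims, ssims[1:])), ssims

    def test_idempotence_at_matched_order(self, nuclei_pair):
        img, _ = nuclei_pair
        cfg = AttackConfig(order=20, output_encoding="float")
        once = attack_image(img, cfg).adversarial
        twice = attack_image(once, cfg).adversarial
        assert mean_ssim(twice, once) >= 0.999

    def test_mean_degradation_over_suite(self, rng):
        """Across many structured images, lower order => lower mean SSIM."""
        from mbada import nuclei_suite

        suite = [img for img, _ in nuclei_suite(20, size=48, seed=100)]
        mean_hi = np.mean([
            attack_image(i, AttackConfig(order=40)).ssim_vs_original for i in suite
        ])
        mean_lo = np.mean([
            attack_image(i, AttackConfig(order=12)).ssim_vs_original for i in suite
        ])
        assert mean_lo <= mean_hi

    def test_rgb_channels_processed_independently(self, rng):
        gray = rng.random((24, 24))
        rgb = np.stack([gray, gray * 0.5, np.clip(gray + 0.1, 0, 1)], axis=-1)
        cfg = AttackConfig(order=8, output_encoding="float")
        res_rgb = attack_image(IntensityImage(rgb), cfg).adversarial.pixels
        for c in range(3):
            res_c = attack_image(IntensityImage(rgb[:, :, c]), cfg).adversarial.pixels
            assert np.abs(res_rgb[:, :, c] - res_c).max() <= 1e-12

    def test_order_above_cap_rejected(self, rng):
        img = IntensityImage(rng.random((16, 32)))
        with pytest.raises(ValueError, match=r"min\(N, M\)-1 = 15"):
            attack_image(img, AttackConfig(order=16))

    def test_per_axis_override(self, rng):
        img = IntensityImage(rng.random((16, 32)))
        res = attack_image(
            img, AttackConfig(order=0, per_axis_orders=(10, 25),
                              output_encoding="float")
        )
        assert res.adversarial.pixels.shape == (16, 32)

    def test_deterministic(self, nuclei_pair):
        img, _ = nuclei_pair
        cfg = AttackConfig(order=15)
        a = attack_image(img, cfg).adversarial.pixels
        b = attack_image(img, cfg).adversarial.pixels
        assert np.array_equal(a, b)

    def test_eight_bit_output_on_grid(self, nuclei_pair):
        img, _ = nuclei_pair
        out = attack_image(img, AttackConfig(order=15)).adversarial.pixels
        assert np.array_equal(out, np.rint(out * 255) / 255)


class TestAttackBatch:
    def _sources(self, n=5, size=32, seed=0):
        from mbada import nuclei_suite

        blobs = 4 if size <= 16 else 8
        return [(f"img{i}", img) for i, (img, _) in
                enumerate(nuclei_suite(n, size=size, seed=seed, blob_count=blobs))]

    def test_count_conservation(self, tmp_path):
        manifest = attack_batch(self._sources(5), AttackConfig(order=20), tmp_path)
        assert len(manifest) == 5
        assert (manifest["status"] == "ok").all()
        for out in manifest["output"]:
            assert Path(out).exists()
            IntensityImage.load(out)  # re-readable

    def test_corrupt_file_isolated(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_text("this is not a png")
        inputs = [p for _, p in []]
        # three good synthetic images written to disk plus one corrupt file
        src_dir = tmp_path / "src"
        src_dir.mkdir()
        paths = []
        for name, img in self._sources(3):
            p = src_dir / f"{name}.png"
            img.save(p)
            paths.append(p)
        paths.insert(1, bad)
        manifest = attack_batch(paths, AttackConfig(order=10), tmp_path / "out")
        assert len(manifest) == 4
        assert (manifest["status"] == "ok").sum() == 3
        assert manifest["status"].str.startswith("error").sum() == 1

    def test_order_recapped_per_image(self, tmp_path):
        manifest = attack_batch(self._sources(2, size=16), AttackConfig(order=100),
                                tmp_path)
        assert (manifest["requested_order"] == 100).all()
        assert (manifest["applied_order"] == 15).all()

    def test_byte_identical_reruns(self, tmp_path):
        cfg = AttackConfig(order=12)
        m1 = attack_batch(self._sources(3), cfg, tmp_path / "a")
        m2 = attack_batch(self._sources(3), cfg, tmp_path / "b")
        for o1, o2 in zip(m1["output"], m2["output"]):
            assert Path(o1).read_bytes() == Path(o2).read_bytes()

    def test_empty_inputs_warn_empty_manifest(self, tmp_path, caplog):
        manifest = attack_batch([], AttackConfig(order=5), tmp_path)
        assert manifest.empty
        assert list(manifest.columns)[:3] == ["input", "height", "width"]
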