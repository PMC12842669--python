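import numpy as np
import pytest

from radnorm.errors import ContractError, DegenerateInputError
from radnorm.image_io import DatasetManifest, GrayImage, ManifestRecord
from radnorm.intensity_norm import (
    DatasetStats,
    NormalizationSpec,
    StandardizationParams,
    adaptive_normalize,
    ablation_variant,
    histogram_standardize,
    minmax_scale,
    quantize_uint8,
    resize_bilinear,
    zscore_apply,
    zscore_fit,
)
from radnorm.phantom import default_config, generate_phantom
from radnorm.roi_crop import CropSpec


def embedded(*pixel_arrays):
    return DatasetManifest(
        tuple(
            ManifestRecord(path=None, label=0, patient_id=f"p{i}", domain="d", pixels=np.asarray(a))
            for i, a in enumerate(pixel_arrays)
        )
    )


class TestDefaults:
    def test_target_constants_full_precision(self):
        p = StandardizationParams()
        assert p.mu_target == 0.4776 * 255
        assert p.sigma_target == 0.2238 * 255
        assert round(p.mu_target, 1) == 121.8
        assert round(p.sigma_target, 1) == 57.1

    def test_sigma_positive(self):
        with pytest.raises(ContractError):
            StandardizationParams(sigma_target=0.0)


class TestMinmaxScale:
    def test_endpoints(self):
        img = GrayImage(np.array([[0, 255]], dtype=np.uint8))
        assert minmax_scale(img).pixels.tolist() == [[0.0, 1.0]]

    def test_forced_arithmetic(self):
        img = GrayImage(np.array([[51]], dtype=np.uint8))
        assert minmax_scale(img).pixels[0, 0] == pytest.approx(0.2)

    def test_constant_image_fixed_range(self):
        img = GrayImage(np.full((3, 3), 128, dtype=np.uint8))
        assert (minmax_scale(img).pixels == 128 / 255).all()

    def test_rejects_non_uint8(self):
        with pytest.raises(ContractError):
            minmax_scale(GrayImage(np.array([[0.5]]), "unit"))

    def test_strictly_monotone(self, rng):
        img = GrayImage(np.arange(256, dtype=np.uint8).reshape(16, 16))
        out = minmax_scale(img).pixels.ravel()
        assert (np.diff(out) > 0).all()


class TestZscore:
    def test_two_point_stats(self):
        m = embedded([[0]], [[2]])
        s = zscore_fit(m)
        assert s.mu_global == 1.0 and s.sigma_global == 1.0 and s.n_images == 2

    def test_constant_dataset_flagged_at_apply(self):
        m = embedded([[5, 5]])
        s = zscore_fit(m)
        assert s.sigma_global == 0.0
        with pytest.raises(DegenerateInputError):
            zscore_apply(GrayImage(np.array([[5]], dtype=np.uint8)), s)

    def test_pooled_pixel_oracle(self):
        # brute force over the 4 pixels of [[0,0]] and [[2,4]]
        pixels = np.array([0.0, 0.0, 2.0, 4.0])
        m = embedded([[0, 0]], [[2, 4]])
        s = zscore_fit(m)
        assert s.mu_global == pytest.approx(pixels.mean())
        assert s.sigma_global == pytest.approx(pixels.std())
        assert s.mu_global == pytest.approx(1.5)

    def test_identity_center(self):
        s = DatasetStats(100.0, 50.0, 3)
        img = GrayImage(np.full((2, 2), 100, dtype=np.uint8))
        assert (zscore_apply(img, s).pixels == 0).all()

    def test_identity_transform(self):
        s = DatasetStats(0.0, 1.0, 1)
        img = GrayImage(np.array([[3, 9]], dtype=np.uint8))
        assert zscore_apply(img, s).pixels.tolist() == [[3.0, 9.0]]

    def test_forced_arithmetic(self):
        s = DatasetStats(100.0, 50.0, 1)
        img = GrayImage(np.array([[200]], dtype=np.uint8))
        assert zscore_apply(img, s).pixels[0, 0] == pytest.approx(2.0)

    def test_monotone(self):
        s = DatasetStats(10.0, 7.0, 1)
        img = GrayImage(np.arange(0, 250, 10, dtype=np.uint8).reshape(5, 5))
        assert (np.diff(zscore_apply(img, s).pixels.ravel()) > 0).all()


class TestHistogramStandardize:
    def test_fixed_point(self):
        # an image already at the target moments is unchanged pre-clip
        base = np.array([121.788 - 57.069, 121.788 + 57.069])
        img = GrayImage(np.tile(base, 50).reshape(10, 10), "standardized")
        out = histogram_standardize(img, clip=False)
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=1e-12)

    def test_constant_image_maps_to_target_mean(self):
        img = GrayImage(np.full((4, 4), 7, dtype=np.uint8))
        out = histogram_standardize(img)
        assert (out.pixels == StandardizationParams().mu_target).all()

    def test_two_pixel_derived_values(self):
        # mu_orig = 50, sigma_orig = 50 -> [64.719, 178.857] pre-clip
        img = GrayImage(np.array([[0, 100]], dtype=np.uint8))
        out = histogram_standardize(img, clip=False)
        np.testing.assert_allclose(out.pixels, [[64.719, 178.857]], atol=1e-12)

    def test_moment_recovery_random_images(self, rng):
        p = StandardizationParams()
        for _ in range(100):
            px = rng.integers(0, 256, size=(17, 23))
            if px.std() == 0:
                continue
            out = histogram_standardize(GrayImage(px.astype(np.uint8)), clip=False)
            assert abs(out.pixels.mean() - p.mu_target) / p.mu_target <= 1e-9
            assert abs(out.pixels.std() - p.sigma_target) / p.sigma_target <= 1e-9

    def test_idempotent_pre_clip(self, rng):
        px = rng.integers(100, 160, size=(12, 12)).astype(np.uint8)
        once = histogram_standardize(GrayImage(px), clip=False)
        assert once.pixels.min() >= 0 and once.pixels.max() <= 255  # no clipping occurred
        twice = histogram_standardize(once, clip=False)
        np.testing.assert_allclose(twice.pixels, once.pixels, rtol=1e-12)

    def test_affine_invariance(self, rng):
        px = rng.integers(0, 60, size=(9, 9)).astype(np.float64)
        a, b = 2.5, 17.0
        out1 = histogram_standardize(GrayImage(px, "standardized"), clip=False)
        out2 = histogram_standardize(GrayImage(a * px + b, "standardized"), clip=False)
        np.testing.assert_allclose(out1.pixels, out2.pixels, atol=1e-9)


class TestResizeBilinear:
    def test_identity(self, rng):
        px = rng.integers(0, 256, size=(5, 7)).astype(np.uint8)
        out = resize_bilinear(GrayImage(px), 5, 7)
        assert np.array_equal(out.pixels, px)

    def test_constant_preserved(self):
        img = GrayImage(np.full((2, 2), 9, dtype=np.uint8))
        assert (resize_bilinear(img, 10, 13).pixels == 9).all()

    def test_corner_aligned_midpoints(self):
        # 2x1 [[0],[255]] -> 4x1 at source positions 0, 1/3, 2/3, 1
        img = GrayImage(np.array([[0.0], [255.0]]), "standardized")
        out = resize_bilinear(img, 4, 1)
        np.testing.assert_allclose(out.pixels.ravel(), [0.0, 85.0, 170.0, 255.0])

    def test_rejects_bad_dims(self, uniform_100):
        with pytest.raises(ContractError):
            resize_bilinear(uniform_100, 0, 10)


class TestAdaptiveAndAblation:
    def test_uniform_composition(self, uniform_100):
        out, crop = adaptive_normalize(uniform_100, NormalizationSpec("adaptive"))
        assert crop.window == (5, 94, 15, 94)
        assert out.shape == (80, 90)
        assert (out.pixels == 122).all()  # round(121.788)

    def test_full_crop_equals_hist_only(self, rng):
        px = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        img = GrayImage(px)
        full = NormalizationSpec("adaptive", crop=CropSpec(0.0, 1.0, 0.0, 1.0))
        adaptive_out, _ = adaptive_normalize(img, full)
        hist_out = ablation_variant(img, NormalizationSpec("hist_only"))
        assert np.array_equal(adaptive_out.pixels, hist_out.pixels)

    def test_phantom_mean_near_target(self):
        cfg = default_config(noise_sd=0.0)
        img, _ = generate_phantom(cfg, "site_b", 1, np.random.default_rng(3))
        out, _ = adaptive_normalize(img, NormalizationSpec("adaptive"))
        # clipping + quantization distortion stays small on realistic content
        assert abs(out.pixels.mean() - 121.788) < 5.0

    def test_crop_only_pure_selection(self, uniform_100):
        out = ablation_variant(uniform_100, NormalizationSpec("crop_only"))
        assert out.shape == (80, 90)
        assert (out.pixels == 50).all()

    def test_hist_only_constant(self):
        img = GrayImage(np.full((6, 6), 3, dtype=np.uint8))
        out = ablation_variant(img, NormalizationSpec("hist_only"))
        assert (out.pixels == 122).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ContractError):
            NormalizationSpec("clahe")
        with pytest.raises(ContractError):
            ablation_variant(
                GrayImage(np.zeros((2, 2), dtype=np.uint8)), NormalizationSpec("adaptive")
            )

    def test_output_size_respected(self, uniform_100):
        spec = NormalizationSpec("adaptive", output_size=(32, 48))
        out, _ = adaptive_normalize(uniform_100, spec)
        assert out.shape == (32, 48)

    def test_quantize_rounds_half_away_from_zero(self):
        img = GrayImage(np.array([[0.5, 1.5, 121.5]]), "standardized")
        assert quantize_uint8(img).pixels.tolist() == [[1, 2, 122]]


class TestDispersionReduction:
    def test_between_domain_variance_collapse(self, noisy_phantom_manifest):
        import pandas as pd

        spec = NormalizationSpec("adaptive")
        rows = []
        for rec in noisy_phantom_manifest:
            img = rec.load()
            rows.append(
                {
                    "minmax": minmax_scale(img).pixels.mean(),
                    "adaptive": adaptive_normalize(img, spec)[0].pixels.mean() / 255.0,
                    "domain": rec.domain,
                }
            )
        per_domain = pd.DataFrame(rows).groupby("domain").mean()
        ratio = per_domain["adaptive"].var() / per_domain["minmax"].var()
        assert ratio < 0.01
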