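"""Enhancement pipeline: unsharp masking, CLAHE, 3-channel merge."""
import numpy as np
import pytest
from scipy import ndimage

import angioseg as ag
from angioseg.preprocess import ParameterError


def gaussian_kernel_2d(sigma, truncate=4.0):
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


class TestUnsharpMask:
    def test_constant_image_is_fixed_point(self):
        img = ag.RawAngiogram(np.full((40, 40), 128, np.uint8))
        out = ag.unsharp_mask(img, radius=3.0, amount=2.5)
        assert np.array_equal(out.pixels, img.pixels)

    def test_amount_zero_is_identity(self, rng):
        img = ag.RawAngiogram(rng.integers(0, 256, (40, 40)).astype(np.uint8))
        out = ag.unsharp_mask(img, radius=2.0, amount=0.0)
        assert np.array_equal(out.pixels, img.pixels)

    def test_matches_brute_force_gaussian_convolution(self):
        # single bright centre pixel; oracle is a dense-kernel convolution
        img = np.zeros((33, 33), np.uint8)
        img[16, 16] = 200
        radius, amount = 1.0, 1.0
        k = gaussian_kernel_2d(radius)
        r = k.shape[0] // 2
        padded = np.pad(img.astype(np.float64), r, mode="symmetric")
        blur = np.zeros_like(img, dtype=np.float64)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                blur[i, j] = (padded[i:i + 2 * r + 1, j:j + 2 * r + 1] * k).sum()
        expected = np.clip(np.rint(img + amount * (img - blur)), 0, 255)
        out = ag.unsharp_mask(ag.RawAngiogram(img), radius, amount).pixels
        assert np.max(np.abs(out.astype(int) - expected.astype(int))) <= 1

    def test_parameter_and_shape_errors(self, rng):
        img = ag.RawAngiogram(rng.integers(0, 256, (40, 40)).astype(np.uint8))
        with pytest.raises(ParameterError):
            ag.unsharp_mask(img, radius=0.0, amount=1.0)
        with pytest.raises(ParameterError):
            ag.RawAngiogram(np.zeros((3, 40, 40), np.uint8))


class TestClahe:
    def test_single_tile_unbounded_clip_equals_global_hist_eq(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = ag.clahe(ag.RawAngiogram(img), clip_limit=np.inf, tile_grid=(1, 1)).pixels
        # independent oracle: classic CDF remapping
        hist = np.bincount(img.ravel(), minlength=256)
        lut = np.clip(np.rint(np.cumsum(hist) * 255.0 / img.size), 0, 255).astype(np.uint8)
        assert np.array_equal(out, lut[img])

    def test_mapping_is_monotone_in_intensity(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = ag.clahe(ag.RawAngiogram(img.repeat(4, 0).repeat(4, 1)),
                       clip_limit=2.0, tile_grid=(1, 1)).pixels
        flat_in = img.repeat(4, 0).repeat(4, 1).ravel()
        order = np.argsort(flat_in, kind="stable")
        assert np.all(np.diff(out.ravel()[order].astype(int)) >= -0)

    def test_range_preserved_on_noise(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = ag.clahe(ag.RawAngiogram(img), 3.0, (8, 8)).pixels
        assert out.dtype == np.uint8 and out.min() >= 0 and out.max() <= 255

    def test_non_divisible_grid_and_errors(self, rng):
        img = ag.RawAngiogram(rng.integers(0, 256, (50, 70)).astype(np.uint8))
        out = ag.clahe(img, 2.0, (3, 7))
        assert out.pixels.shape == (50, 70)
        with pytest.raises(ParameterError):
            ag.clahe(img, 2.0, (128, 2))
        with pytest.raises(ParameterError):
            ag.clahe(img, -1.0, (2, 2))


class TestPipeline:
    def test_three_channels_of_input_shape(self, synthetic_sample):
        pre = ag.preprocess_pipeline(synthetic_sample.image)
        assert pre.channels.shape == (3,) + synthetic_sample.image.pixels.shape
        assert pre.channel_roles == ("usm", "clahe_a", "clahe_b")

    def test_constant_input_usm_channel_unchanged(self):
        img = ag.RawAngiogram(np.full((64, 64), 90, np.uint8))
        pre = ag.preprocess_pipeline(img)
        assert np.array_equal(pre.channels[0], img.pixels)

    def test_deterministic(self, synthetic_sample):
        a = ag.preprocess_pipeline(synthetic_sample.image).channels
        b = ag.preprocess_pipeline(synthetic_sample.image).channels
        assert np.array_equal(a, b)

    def test_enhancement_does_not_reduce_vessel_contrast(self, synthetic_sample):
        mask = synthetic_sample.mask.astype(bool)
        annulus = ndimage.binary_dilation(mask, iterations=5) & ~mask
        raw = synthetic_sample.image.pixels.astype(float)
        enh = ag.preprocess_pipeline(synthetic_sample.image).channels.mean(axis=0)
        raw_contrast = raw[annulus].mean() - raw[mask].mean()
        enh_contrast = enh[annulus].mean() - enh[mask].mean()
        assert enh_contrast >= raw_contrast

    def test_param_validation(self):
        with pytest.raises(ParameterError):
            ag.PreprocessParams(clahe_a=ag.ClaheParams(2.0, (8, 8)),
                                clahe_b=ag.ClaheParams(2.0, (8, 8)))
        with pytest.raises(ParameterError):
            ag.PreprocessParams(usm_radius=-1.0)

    def test_float_dialect_round_trip(self, rng):
        u8 = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        out_u8 = ag.unsharp_mask(ag.RawAngiogram(u8), 2.0, 1.5).pixels
        out_f = ag.unsharp_mask(ag.RawAngiogram(u8 / 255.0), 2.0, 1.5).pixels
        assert out_f.dtype.kind == "f" and out_f.max() <= 1.0
        assert np.array_equal(np.rint(out_f * 255).astype(np.uint8), out_u8)
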