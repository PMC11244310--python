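"""Noise-adaptive discrimination filter: detection, replacement, full filter."""

import numpy as np
import pytest

from gravessel.nadf import FilterConfig, detect_noise, nadf_gra, replace_noise
from gravessel.synthetic import SynthConfig, add_salt_pepper, generate


def _clamp(idx, n):
    return min(max(idx, 0), n - 1)


def _naive_detect(img):
    """Literal per-pixel transcription of the detection rule (replicate border)."""
    img = np.asarray(img, dtype=float)
    M, N = img.shape
    flags = np.ones((M, N), dtype=np.uint8)
    for i in range(M):
        for j in range(N):
            vals = [
                img[_clamp(i + di, M), _clamp(j + dj, N)]
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
            ]
            v = float(np.median(vals))
            coeffs = [1.0 / (1.0 + abs(v - x)) for x in vals]
            order = sorted(range(9), key=lambda k: (coeffs[k], k))
            if order.index(4) + 1 <= 3:
                flags[i, j] = 0
    return flags


def _naive_replace(img, flags):
    """Sequential in-place repair, written independently of the package loop."""
    out = np.asarray(img, dtype=float).copy()
    M, N = out.shape
    for i in range(M):
        for j in range(N):
            if flags[i, j] == 1:
                continue
            vals, normals = [], []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    r, c = _clamp(i + di, M), _clamp(j + dj, N)
                    vals.append(out[r, c])
                    if (di, dj) != (0, 0) and flags[r, c] == 1:
                        normals.append(out[r, c])
            if normals:
                v = float(np.median(vals))
                weights = [1.0 / (1.0 + abs(v - f)) for f in normals]
                out[i, j] = sum(w * f for w, f in zip(weights, normals)) / sum(weights)
            else:
                vals5 = [
                    out[_clamp(i + di, M), _clamp(j + dj, N)]
                    for di in (-2, -1, 0, 1, 2)
                    for dj in (-2, -1, 0, 1, 2)
                ]
                out[i, j] = float(np.median(vals5))
    return out


class TestDetection:
    def test_constant_image_is_all_normal(self):
        assert detect_noise(np.full((8, 8), 42.0)).all()

    @pytest.mark.parametrize("impulse", [255.0, 0.0])
    def test_single_interior_impulse_is_flagged(self, impulse):
        img = np.full((9, 9), 100.0)
        img[4, 5] = impulse
        flags = detect_noise(img)
        assert flags[4, 5] == 0
        flags[4, 5] = 1
        assert flags.all()

    def test_matches_naive_reference(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, size=(20, 20)).astype(float)
            np.testing.assert_array_equal(detect_noise(img), _naive_detect(img))

    def test_rejects_too_small(self):
        with pytest.raises(ValueError):
            detect_noise(np.zeros((2, 2)))


class TestReplacement:
    def test_all_normal_is_identity(self, rng):
        img = rng.integers(0, 256, size=(10, 10)).astype(float)
        out = replace_noise(img, np.ones_like(img, dtype=np.uint8))
        np.testing.assert_array_equal(out, img)

    def test_salt_on_flat_restored_exactly(self):
        img = np.full((7, 7), 100.0)
        img[3, 3] = 255.0
        flags = np.ones((7, 7), dtype=np.uint8)
        flags[3, 3] = 0
        out = replace_noise(img, flags)
        assert out[3, 3] == pytest.approx(100.0)

    def test_block_detection_follows_median_breakdown(self):
        """For a 3x3 noise block only corner pixels can be detected (corner
        windows hold 4 noisy of 9 values, so the median stays clean; edge and
        center windows hold a noisy majority that captures the median), and
        the stable tie-break spares the last corner, whose coefficient ties
        come entirely before the center position."""
        img = np.full((7, 7), 50.0)
        img[2:5, 2:5] = 255.0
        flags = detect_noise(img)
        expected = np.ones((7, 7), dtype=np.uint8)
        for i, j in ((2, 2), (2, 4), (4, 2)):
            expected[i, j] = 0
        np.testing.assert_array_equal(flags, expected)
        out = replace_noise(img, flags)
        np.testing.assert_array_equal(out[flags == 1], img[flags == 1])
        corner_values = out[flags == 0]
        assert np.all(corner_values < 255.0) and np.all(corner_values >= 50.0)

    def test_inplace_traversal_heals_large_noise_blocks(self):
        """With a hand-flagged 5x5 noise block, the raster-order in-place pass
        feeds repaired values into later 5x5 median fallbacks and heals almost
        the whole block; the two-pass variant, reading only original values,
        leaves the block interior at the noise level."""
        img = np.full((9, 9), 50.0)
        img[2:7, 2:7] = 255.0
        flags = np.ones((9, 9), dtype=np.uint8)
        flags[2:7, 2:7] = 0
        healed = replace_noise(img, flags, FilterConfig(inplace=True))
        two_pass = replace_noise(img, flags, FilterConfig(inplace=False))
        unhealed_inplace = int((healed[2:7, 2:7] == 255.0).sum())
        unhealed_two_pass = int((two_pass[2:7, 2:7] == 255.0).sum())
        assert unhealed_inplace <= 2
        assert unhealed_two_pass >= 6
        assert unhealed_inplace < unhealed_two_pass

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            replace_noise(np.zeros((5, 5)), np.ones((4, 5)))


class TestFullFilter:
    def test_flat_image_is_fixed_point(self):
        img = np.full((12, 12), 77.0)
        np.testing.assert_array_equal(nadf_gra(img), img)

    def test_matches_naive_reference(self, rng):
        for _ in range(3):
            img = rng.integers(0, 256, size=(20, 20)).astype(float)
            img = add_salt_pepper(img, 0.1, np.random.default_rng(1))
            expected = _naive_replace(img, _naive_detect(img))
            np.testing.assert_allclose(nadf_gra(img), expected, atol=1e-9)

    def test_output_within_input_range(self, rng):
        img = add_salt_pepper(rng.uniform(40, 200, size=(24, 24)), 0.08, 3)
        out = nadf_gra(img)
        assert out.min() >= img.min() and out.max() <= img.max()

    def test_flag_fraction_monotone_in_noise_density(self):
        base = generate(SynthConfig(seed=7, sp_density=0.0, gaussian_sigma=0.0)).clean
        fractions = []
        for density in (0.01, 0.05, 0.10):
            noisy = add_salt_pepper(base, density, seed=123)
            fractions.append(1.0 - detect_noise(noisy).mean())
        assert fractions == sorted(fractions)

    def test_denoising_reduces_error_to_clean(self):
        sample = generate(SynthConfig(seed=3))
        mae_noisy = np.abs(sample.image - sample.clean).mean()
        mae_filtered = np.abs(nadf_gra(sample.image) - sample.clean).mean()
        assert mae_filtered < mae_noisy

    @pytest.mark.parametrize("impulse", [255.0, 0.0])
    def test_impulse_on_gradient_restored(self, impulse):
        """Interior pixels: the impulse is repaired to within one level and
        the gradient elsewhere is untouched (borders excluded — replicate
        padding can flag extremal corner values)."""
        yy, xx = np.mgrid[0:15, 0:15]
        clean = 60.0 + 2.0 * yy + 3.0 * xx
        img = clean.copy()
        img[7, 7] = impulse
        out = nadf_gra(img)
        err = np.abs(out - clean)[1:-1, 1:-1]
        assert err.max() <= 1.0
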