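import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braingmm.segment import (
    IntensityHistogram,
    NoTumorDetectedError,
    between_class_variance,
    dice,
    extract_tumor_mask,
    histogram,
    otsu_multithreshold,
    quantize,
    skull_strip,
)


def brute_force_otsu(hist, m):
    """Independent exhaustive maximizer (plain Python loops)."""
    centers = hist.centers
    p = hist.counts / hist.counts.sum()
    best, best_combo = -np.inf, None
    for combo in itertools.combinations(range(centers.size - 1), m):
        bounds = (0,) + tuple(c + 1 for c in combo) + (centers.size,)
        score = 0.0
        for k in range(m + 1):
            seg_p = p[bounds[k] : bounds[k + 1]]
            w = seg_p.sum()
            if w > 0:
                s = (seg_p * centers[bounds[k] : bounds[k + 1]]).sum()
                score += s * s / w
        # same tie tolerance as the implementation: near-equal scores keep
        # the lexicographically earlier tuple
        if best_combo is None or score > best + 1e-10 * max(abs(best), 1.0):
            best, best_combo = score, combo
    return centers[list(best_combo)]


class TestHistogram:
    def test_constant_image_single_bin(self):
        h = histogram(np.full((4, 4), 100.0), n_bins=256)
        assert np.count_nonzero(h.counts) == 1
        assert h.counts.sum() == 16

    def test_mask_conservation(self, rng):
        img = rng.uniform(0, 255, (10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:3, :4] = True
        h = histogram(img, mask=mask)
        assert h.counts.sum() == mask.sum()

    def test_direct_tally(self):
        img = np.array([[0.0, 0.0], [128.0, 255.0]])
        h = histogram(img, n_bins=256)
        nonzero = h.counts[h.counts > 0]
        assert sorted(nonzero.tolist()) == [1, 1, 2]
        assert h.counts[0] == 2  # both zeros in the first bin
        assert h.counts[-1] == 1  # max value in the last bin

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            histogram(np.zeros((4, 4)), mask=np.zeros((4, 4), dtype=bool))


class TestOtsu:
    def test_two_delta_spikes_tie_breaks_low(self):
        counts = np.zeros(256)
        counts[50] = 10
        counts[200] = 10
        h = IntensityHistogram.integer_bins(counts)
        thr = otsu_multithreshold(h, m=1)
        assert thr[0] == 50.0

    def test_uniform_histogram_matches_brute_force(self):
        h = IntensityHistogram.integer_bins(np.ones(64))
        assert np.array_equal(otsu_multithreshold(h, 1), brute_force_otsu(h, 1))

    def test_three_gaussian_histogram_m2_matches_brute_force(self, rng):
        from conftest import RECOVERY_MIXTURE, sample_mixture

        x = np.clip(sample_mixture(rng, RECOVERY_MIXTURE, 5000), 0, 255)
        h = histogram(x.reshape(50, 100), n_bins=64)
        assert np.array_equal(otsu_multithreshold(h, 2), brute_force_otsu(h, 2))

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_random_histograms_match_brute_force(self, m, rng):
        for _ in range(10):
            n_bins = int(rng.integers(m + 2, 33))
            counts = rng.integers(0, 40, n_bins).astype(float)
            while np.count_nonzero(counts) < m + 1:
                counts = rng.integers(0, 40, n_bins).astype(float)
            h = IntensityHistogram.integer_bins(counts)
            assert np.array_equal(otsu_multithreshold(h, m), brute_force_otsu(h, m))

    def test_too_few_occupied_bins_rejected(self):
        counts = np.zeros(16)
        counts[3] = 5
        counts[9] = 5
        with pytest.raises(ValueError, match="occupied"):
            otsu_multithreshold(IntensityHistogram.integer_bins(counts), m=2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 50), min_size=8, max_size=24),
        m=st.sampled_from([1, 2]),
        seed=st.integers(0, 1000),
    )
    def test_returned_thresholds_dominate_random_tuples(self, counts, m, seed):
        counts = np.asarray(counts, dtype=float)
        if np.count_nonzero(counts) < m + 1:
            return
        h = IntensityHistogram.integer_bins(counts)
        thr = otsu_multithreshold(h, m)
        best = between_class_variance(h, thr)
        rng = np.random.default_rng(seed)
        for _ in range(10):
            cand = rng.choice(h.centers[:-1], size=m, replace=False)
            assert best >= between_class_variance(h, cand) - 1e-9

    def test_variance_not_below_skimage_choice(self, rng):
        """Cross-check against scikit-image's multi-Otsu on the same histogram."""
        from skimage.filters import threshold_multiotsu

        x = np.clip(rng.normal(120, 40, (64, 64)), 0, 255)
        h = histogram(x, n_bins=64)
        ours = otsu_multithreshold(h, 2)
        theirs = threshold_multiotsu(hist=(h.counts, h.centers), classes=3)
        assert between_class_variance(h, ours) >= between_class_variance(h, theirs) - 1e-9


class TestQuantize:
    def test_empty_threshold_set(self):
        img = np.arange(9.0).reshape(3, 3)
        assert np.all(quantize(img, []) == 0)

    def test_constant_above_threshold(self):
        assert np.all(quantize(np.full((2, 2), 10.0), [5.0]) == 1)

    def test_band_convention(self):
        img = np.array([0.0, 100.0, 150.0, 255.0])
        assert quantize(img, [50.0, 200.0]).tolist() == [0, 1, 1, 2]
        # band tops are inclusive
        assert quantize(np.array([50.0]), [50.0, 200.0]).tolist() == [0]

    def test_label_count_bounded(self, rng):
        img = rng.uniform(0, 255, (12, 12))
        labels = quantize(img, [60.0, 120.0, 180.0])
        assert labels.max() <= 3 and labels.min() >= 0


class TestSkullStrip:
    def test_background_only_rejected(self):
        with pytest.raises(ValueError, match="no interior"):
            skull_strip(np.zeros((32, 32), dtype=int))

    def test_phantom_brain_mask(self, default_truth, segmented):
        brain = segmented["brain_mask"]
        assert (brain & default_truth.skull_mask).sum() == 0
        interior = default_truth.normal_mask | default_truth.tumor_mask
        assert dice(brain, interior) >= 0.95


class TestExtractTumor:
    def test_phantom_tumor_dice(self, default_truth, segmented):
        assert dice(segmented["tumor_mask"], default_truth.tumor_mask) >= 0.90

    def test_largest_component_rule(self):
        labels = np.zeros((60, 60), dtype=int)
        brain = np.ones((60, 60), dtype=bool)
        labels[5:30, 5:25] = 2  # 500 px
        labels[40:49, 40:49] = 2  # 81 px
        out = extract_tumor_mask(labels, brain, band=2, opening_radius=0, min_area=30)
        assert out[10, 10] and not out[44, 44]
        assert out.sum() == 500

    def test_tumor_band_outside_brain_is_no_tumor(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[0:3, 0:3] = 2
        brain = np.zeros((20, 20), dtype=bool)
        brain[8:16, 8:16] = True
        with pytest.raises(NoTumorDetectedError):
            extract_tumor_mask(labels, brain, band=2)

    def test_output_within_brain(self, segmented):
        assert not (segmented["tumor_mask"] & ~segmented["brain_mask"]).any()
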