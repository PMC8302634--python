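"""Adaptive Otsu quantifier: threshold selection, equalisation, FI recovery."""

import numpy as np
import pytest

from fatquant import (DataError, PhantomSpec, equalize_roi, generate_phantom,
                      otsu_threshold, quantify_fat, roi_histogram)
from fatquant.adaptive_otsu import render_fat_image


def brute_force_otsu(hist):
    """Independent oracle: exhaustive between-class variance in plain Python."""
    hist = [float(h) for h in hist]
    total = sum(hist)
    levels = list(range(256))
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            v = 0.0
        else:
            mu0 = sum(l * hist[l] for l in levels[: t + 1]) / w0
            mu1 = sum(l * hist[l] for l in levels[t + 1:]) / w1
            v = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    occupied = [l for l in levels if hist[l] > 0]
    if len(occupied) == 1:
        return occupied[0]
    return best_t


def uniform_slice(values, shape=(32, 32)):
    """Slice whose first len(values) pixels are `values`; mask covering them."""
    arr = np.zeros(shape, dtype=np.uint8)
    mask = np.zeros(shape, dtype=bool)
    flat = arr.ravel()
    flat[: len(values)] = values
    mask.ravel()[: len(values)] = True
    return arr, mask


class TestRoiHistogram:
    def test_single_value_roi(self):
        arr, mask = uniform_slice([71] * 10)
        hist = roi_histogram(arr, mask)
        assert hist[71] == 10 and hist.sum() == 10

    def test_two_spike_roi(self):
        arr, mask = uniform_slice([50] * 100 + [200] * 100, shape=(32, 32))
        hist = roi_histogram(arr, mask)
        assert hist[50] == 100 and hist[200] == 100 and hist.sum() == 200

    def test_sums_to_mask_area_vs_pixel_scan(self, rng):
        arr = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        mask = rng.random((32, 32)) < 0.4
        hist = roi_histogram(arr, mask)
        brute = np.zeros(256, dtype=int)
        for v, m in zip(arr.ravel(), mask.ravel()):
            if m:
                brute[v] += 1
        np.testing.assert_array_equal(hist, brute)

    def test_empty_mask_is_error(self):
        with pytest.raises(DataError):
            roi_histogram(np.zeros((32, 32), dtype=np.uint8), np.zeros((32, 32), bool))


class TestOtsuThreshold:
    def test_equal_two_spike_ties_to_lowest(self):
        hist = np.zeros(256)
        hist[50] = hist[200] = 100
        assert otsu_threshold(hist) == 50

    def test_single_spike_returns_its_level(self):
        hist = np.zeros(256)
        hist[90] = 500
        assert otsu_threshold(hist) == 90  # nothing classifies as fat downstream

    def test_all_zero_histogram_is_error(self):
        with pytest.raises(DataError):
            otsu_threshold(np.zeros(256))

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(200):
            hist = rng.integers(0, 50, 256)
            hist[rng.random(256) < 0.7] = 0
            if hist.sum() == 0:
                hist[int(rng.integers(256))] = 5
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    def test_agrees_with_skimage_on_bimodal_data(self, rng):
        from skimage.filters import threshold_otsu as sk_otsu

        for _ in range(20):
            vals = np.concatenate([
                rng.normal(80, 12, 4000), rng.normal(190, 12, 2000),
            ])
            vals = np.clip(np.round(vals), 0, 255).astype(np.uint8)
            hist = np.bincount(vals, minlength=256)
            ours = otsu_threshold(hist)
            theirs = int(sk_otsu(hist=(hist, np.arange(256))))
            assert abs(ours - theirs) <= 1  # conventions differ by half a bin at most

    def test_threshold_above_roi_max_classifies_nothing(self):
        arr, mask = uniform_slice(list(range(40, 72)) * 4)
        res = quantify_fat(arr, mask, min_separability=0.0)
        above = arr[mask] > 93
        assert above.sum() == 0  # ROI max is 71


class TestEqualizeRoi:
    def test_outside_pixels_bit_exact(self, rng):
        arr = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        mask = np.zeros((48, 48), bool)
        mask[10:30, 10:30] = True
        out = equalize_roi(arr, mask)
        np.testing.assert_array_equal(out.pixels[~mask], arr[~mask])

    def test_uniform_roi_maps_near_identity(self):
        vals = np.tile(np.arange(256, dtype=np.uint8), 4)
        arr, mask = uniform_slice(vals, shape=(32, 32))
        out = equalize_roi(arr, mask)
        diff = out.pixels[mask].astype(int) - arr[mask].astype(int)
        assert np.abs(diff).max() <= 1

    def test_two_valued_roi_standard_cdf_levels(self):
        arr, mask = uniform_slice([10] * 50 + [20] * 50)
        out = equalize_roi(arr, mask)
        got = set(np.unique(out.pixels[mask]))
        assert got == {128, 255}  # round(255 * {0.5, 1.0})

    def test_mapping_monotone(self, rng):
        arr = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        mask = rng.random((48, 48)) < 0.5
        out = equalize_roi(arr, mask).pixels
        src, dst = arr[mask].astype(int), out[mask].astype(int)
        order = np.argsort(src, kind="stable")
        assert (np.diff(dst[order]) >= 0).all()

    def test_single_valued_roi_passthrough(self):
        arr, mask = uniform_slice([100] * 64)
        out = equalize_roi(arr, mask)
        np.testing.assert_array_equal(out.pixels, arr)


class TestQuantifyFat:
    def test_noiseless_phantom_recovery(self):
        spec = PhantomSpec(image_size=128, fat_fraction_true=0.30, muscle_intensity_mean=90,
                           fat_intensity_mean=190, intensity_sd=0.0, seed=21)
        case = generate_phantom(spec)
        res = quantify_fat(case.slice, case.masks.muscle)
        assert abs(res.fatty_infiltration_pct - 30.0) <= 1.0

    def test_gate_brackets_sd_35(self):
        # two equal spikes a, b have population SD |b-a|/2
        arr_lo, mask = uniform_slice([90] * 50 + [159] * 50)   # SD 34.5
        arr_hi, _ = uniform_slice([90] * 50 + [161] * 50)      # SD 35.5
        assert not quantify_fat(arr_lo, mask).equalization_applied
        assert quantify_fat(arr_hi, mask).equalization_applied

    def test_fat_free_muscle_reads_near_zero(self):
        case = generate_phantom(PhantomSpec(image_size=128, fat_fraction_true=0.0,
                                            intensity_sd=0.0, seed=3))
        res = quantify_fat(case.slice, case.masks.muscle)
        assert res.fatty_infiltration_pct <= 1.0

    def test_noisy_fat_free_guarded_by_separability(self):
        case = generate_phantom(PhantomSpec(image_size=128, fat_fraction_true=0.0,
                                            intensity_sd=10.0, seed=3))
        res = quantify_fat(case.slice, case.masks.muscle)
        assert not res.separable
        assert res.fatty_infiltration_pct == 0.0

    def test_fat_mask_inside_roi_and_pct_consistent(self, mid_phantom):
        res = quantify_fat(mid_phantom.slice, mid_phantom.masks.muscle)
        assert not (res.fat_mask & ~mid_phantom.masks.muscle).any()
        pct = 100.0 * res.fat_mask.sum() / mid_phantom.masks.muscle_area
        assert res.fatty_infiltration_pct == pytest.approx(pct)

    def test_roi_floor(self):
        arr, mask = uniform_slice([10] * 8)
        with pytest.raises(DataError):
            quantify_fat(arr, mask)

    def test_distractors_never_influence_result(self):
        base = dict(image_size=128, occupation_ratio_true=0.6, fat_fraction_true=0.25,
                    intensity_sd=0.0, seed=17)
        a = generate_phantom(PhantomSpec(n_distractors=0, **base))
        b = generate_phantom(PhantomSpec(n_distractors=8, **base))
        ra = quantify_fat(a.slice, a.masks.muscle)
        rb = quantify_fat(b.slice, b.masks.muscle)
        assert ra.threshold == rb.threshold
        assert ra.fatty_infiltration_pct == rb.fatty_infiltration_pct
        np.testing.assert_array_equal(ra.fat_mask, rb.fat_mask)

    def test_fi_strictly_increasing_in_true_fat(self):
        fis = []
        for frac in np.arange(0.0, 0.61, 0.1):
            case = generate_phantom(PhantomSpec(image_size=128, fat_fraction_true=float(frac),
                                                intensity_sd=0.0, seed=30))
            fis.append(quantify_fat(case.slice, case.masks.muscle).fatty_infiltration_pct)
        assert all(b > a for a, b in zip(fis, fis[1:]))

    def test_render_white_fat_black_muscle(self, mid_phantom):
        res = quantify_fat(mid_phantom.slice, mid_phantom.masks.muscle)
        img = render_fat_image(res, mid_phantom.masks.muscle)
        assert set(np.unique(img)) <= {0, 255}
        assert (img == 255).sum() == res.fat_mask.sum()
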