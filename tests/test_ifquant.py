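"""Immunofluorescence scoring against brute-force pixel-loop oracles."""

import numpy as np
import pytest

from monoquant import ifquant, synthio
from monoquant.errors import (
    DegenerateImageError,
    EmptyForegroundError,
    InsufficientFieldsError,
    PairingError,
)
from monoquant.ifquant import ImageFieldPair


def otsu_mask_bruteforce(img):
    """Exhaustive between-class-variance maximization over every candidate
    threshold of a small-integer image (independent of skimage)."""
    img = np.asarray(img)
    vals = np.arange(img.min(), img.max() + 1)
    hist = np.array([(img == v).sum() for v in vals], dtype=float)
    p = hist / hist.sum()
    best_t, best_var = None, -1.0
    for i in range(1, len(vals)):
        w0, w1 = p[:i].sum(), p[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[:i] * vals[:i]).sum() / w0
        mu1 = (p[i:] * vals[i:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, vals[i - 1]
    return img > best_t


class TestBackgroundMask:
    def test_fixed_threshold_all_zero(self):
        assert not ifquant.background_mask(np.zeros((4, 4)), "fixed", 0).any()

    def test_otsu_perfect_bimodality(self):
        img = np.zeros((10, 10))
        img[5:] = 1000
        mask = ifquant.background_mask(img, "otsu")
        assert np.array_equal(mask, img == 1000)

    def test_otsu_matches_exhaustive_search(self, rng):
        # bimodal small-integer field so histogram binning is exact
        img = np.where(
            rng.uniform(size=(40, 40)) < 0.3,
            rng.integers(120, 200, (40, 40)),
            rng.integers(0, 50, (40, 40)),
        )
        mask = ifquant.background_mask(img, "otsu")
        assert np.array_equal(mask, otsu_mask_bruteforce(img))

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            ifquant.background_mask(np.full((5, 5), 7.0), "otsu")


def pixel_loop_field_intensity(field, slide_dapi_mean, threshold):
    total, n = 0.0, 0
    for row in field.marker:
        for px in row:
            if px > threshold:
                total += float(px)
                n += 1
    return (total / n) / slide_dapi_mean


def pixel_loop_nuclear(field, threshold):
    m_sum = d_sum = 0.0
    n = 0
    for i in range(field.dapi.shape[0]):
        for j in range(field.dapi.shape[1]):
            if field.dapi[i, j] > threshold:
                m_sum += float(field.marker[i, j])
                d_sum += float(field.dapi[i, j])
                n += 1
    return (m_sum / n) / (d_sum / n)


class TestFieldScores:
    def test_intensity_arithmetic(self):
        marker = np.array([[0, 0], [200, 200]], dtype=float)
        fld = ImageFieldPair(dapi=np.full((2, 2), 10.0), marker=marker)
        score = ifquant.field_intensity_score(fld, slide_dapi_mean=100.0,
                                              mask_method="fixed", mask_param=50)
        assert score == pytest.approx(2.0)

    def test_nuclear_marker_identical_to_dapi_is_one(self):
        dapi = np.array([[0, 100], [100, 0]], dtype=float)
        fld = ImageFieldPair(dapi=dapi, marker=dapi.copy())
        assert ifquant.nuclear_localization_score(fld, "fixed", 50) == pytest.approx(1.0)

    def test_nuclear_marker_twice_dapi_is_two(self):
        dapi = np.array([[0, 100], [120, 0]], dtype=float)
        fld = ImageFieldPair(dapi=dapi, marker=2 * dapi)
        assert ifquant.nuclear_localization_score(fld, "fixed", 50) == pytest.approx(2.0)

    def test_vectorized_scores_match_pixel_loop(self, rng):
        control, _, _ = synthio.gen_if_slide_pair(n_fields=1, seed=9, field_shape=(64, 64))
        fld = control[0]
        t = 500.0
        score = ifquant.field_intensity_score(fld, 1000.0, "fixed", t)
        assert score == pytest.approx(pixel_loop_field_intensity(fld, 1000.0, t), rel=1e-9)
        nuc = ifquant.nuclear_localization_score(fld, "fixed", t)
        assert nuc == pytest.approx(pixel_loop_nuclear(fld, t), rel=1e-9)

    def test_empty_foreground_raises(self):
        fld = ImageFieldPair(dapi=np.ones((3, 3)), marker=np.ones((3, 3)))
        with pytest.raises(EmptyForegroundError):
            ifquant.field_intensity_score(fld, 1.0, "fixed", 10)
        with pytest.raises(EmptyForegroundError):
            ifquant.nuclear_localization_score(fld, "fixed", 10)


class TestScaleInvariance:
    def test_joint_rescale_leaves_scores_invariant(self):
        control, _, _ = synthio.gen_if_slide_pair(n_fields=5, seed=4, field_shape=(64, 64))
        q1 = ifquant.summarize_slide(control)
        scaled = [
            ImageFieldPair(f.dapi * 0.5, f.marker * 0.5, f.field_id, f.slide_id)
            for f in control
        ]
        q2 = ifquant.summarize_slide(scaled)
        assert q2.slide_mean_intensity == pytest.approx(q1.slide_mean_intensity, rel=1e-6)
        assert q2.slide_mean_nuclear == pytest.approx(q1.slide_mean_nuclear, rel=1e-6)

    def test_marker_only_rescale_multiplies_scores(self):
        control, _, _ = synthio.gen_if_slide_pair(n_fields=1, seed=4, field_shape=(64, 64))
        fld = control[0]
        scaled = ImageFieldPair(fld.dapi, fld.marker.astype(float) * 3.0,
                                fld.field_id, fld.slide_id, bit_depth=18)
        # nuclear mask lives on the (unchanged) DAPI channel
        nuc1 = ifquant.nuclear_localization_score(fld, "fixed", 400)
        nuc2 = ifquant.nuclear_localization_score(scaled, "fixed", 400)
        assert nuc2 == pytest.approx(3 * nuc1, rel=1e-9)
        # intensity mask lives on the marker channel; threshold scales with it
        i1 = ifquant.field_intensity_score(fld, 1000.0, "fixed", 400)
        i2 = ifquant.field_intensity_score(scaled, 1000.0, "fixed", 1200)
        assert i2 == pytest.approx(3 * i1, rel=1e-9)


class TestSummarizeSlide:
    def test_identical_fields_mean_equals_field_score(self):
        fld, _, _ = synthio.gen_if_slide_pair(n_fields=1, seed=2, field_shape=(64, 64))
        fields = [
            ImageFieldPair(fld[0].dapi, fld[0].marker, field_id=f"f{i}") for i in range(5)
        ]
        q = ifquant.summarize_slide(fields)
        assert q.n_fields == 5
        vals = list(q.per_field_nuclear.values())
        assert q.slide_mean_nuclear == pytest.approx(vals[0])

    def test_field_order_permutation_invariant(self):
        control, _, _ = synthio.gen_if_slide_pair(n_fields=6, seed=5, field_shape=(64, 64))
        q1 = ifquant.summarize_slide(control)
        q2 = ifquant.summarize_slide(control[::-1])
        assert q1.slide_mean_intensity == pytest.approx(q2.slide_mean_intensity)
        assert q1.slide_mean_nuclear == pytest.approx(q2.slide_mean_nuclear)

    def test_fewer_than_five_usable_fields_raises(self):
        control, _, _ = synthio.gen_if_slide_pair(n_fields=4, seed=5, field_shape=(64, 64))
        with pytest.raises(InsufficientFieldsError):
            ifquant.summarize_slide(control)

    def test_matches_hand_computed_means(self):
        control, _, _ = synthio.gen_if_slide_pair(n_fields=5, seed=8, field_shape=(64, 64))
        q = ifquant.summarize_slide(control, mask_method="fixed", mask_param=600)
        dapi_pixels = np.concatenate(
            [f.dapi[f.dapi > 600].astype(float) for f in control]
        )
        by_hand = []
        for f in control:
            fg = f.marker[f.marker > 600].astype(float)
            by_hand.append(fg.mean() / dapi_pixels.mean())
        assert q.slide_mean_intensity == pytest.approx(np.mean(by_hand), rel=1e-12)


class TestDonorComparison:
    def _quant(self, value):
        return ifquant.SlideQuant({}, {}, value, value, 5)

    def test_paired_t_on_slide_means(self):
        control = {d: self._quant(v) for d, v in zip("abc", [1.0, 2.0, 3.0])}
        treated = {d: self._quant(v) for d, v in zip("abc", [2.0, 4.0, 6.0])}
        res = ifquant.compare_donor_pairs(control, treated, metric="nuclear")
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2

    def test_mismatched_donors_raise(self):
        with pytest.raises(PairingError):
            ifquant.compare_donor_pairs(
                {"a": self._quant(1), "b": self._quant(2)},
                {"a": self._quant(1), "c": self._quant(2)},
            )
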