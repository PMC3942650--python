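"""Densitometry: inversion, normalisation, mean+2SD labeling, aggregation."""

import numpy as np
import pytest

from ratabr.densitometry import (
    MicrographField,
    aggregate,
    label_profiles,
    measure_field,
    normalize_field,
    quantify_field,
    to_inverted_gray,
)
from ratabr.errors import InputError
from ratabr.synthetic_data import FieldDesign, simulate_histology_cohort, simulate_micrograph


def field_from(pixels, **kw):
    return MicrographField(pixels=np.asarray(pixels), **kw)


class TestInvertedGray:
    def test_white_maps_to_zero(self):
        rgb = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert np.all(to_inverted_gray(rgb) == 0)

    def test_red_absent_dark_pixel_maps_to_255(self):
        rgb = np.zeros((64, 64, 3), dtype=np.uint8)
        rgb[..., 1] = 80  # green/blue content is ignored
        rgb[..., 2] = 200
        assert np.all(to_inverted_gray(rgb) == 255)

    def test_output_is_255_minus_red_everywhere(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        out = to_inverted_gray(rgb)
        np.testing.assert_array_equal(out, 255 - rgb[..., 0])

    def test_idempotent_on_flagged_inverted_input(self):
        gray = np.random.default_rng(1).integers(0, 256, (64, 64)).astype(np.uint8)
        np.testing.assert_array_equal(to_inverted_gray(gray, already_inverted=True), gray)

    def test_16bit_rescaled(self):
        img = np.full((64, 64), 65535, dtype=np.uint16)
        assert np.all(to_inverted_gray(img, already_inverted=True) == 255)


class TestNormalize:
    def test_full_range_image_is_fixed_point(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 256, (128, 128)).astype(np.uint8)
        out = normalize_field(field_from(x))
        p1, p99 = np.percentile(x, [1, 99])
        expected = np.clip((x.astype(float) - p1) * 255 / (p99 - p1), 0, 255)
        np.testing.assert_allclose(out.pixels, expected)

    def test_affine_gray_invariance(self):
        """Normalisation cancels affine gray-level changes exactly."""
        rng = np.random.default_rng(3)
        x = rng.integers(10, 200, (96, 96)).astype(float)
        a, b = 1.1, 5.0
        out1 = normalize_field(field_from(x))
        out2 = normalize_field(field_from(a * x + b))
        np.testing.assert_allclose(out1.pixels, out2.pixels, atol=1e-9)

    def test_constant_image_returned_with_warning(self):
        fld = field_from(np.full((64, 64), 7, dtype=np.uint8))
        out = normalize_field(fld)
        assert out.normalize_warning
        np.testing.assert_array_equal(out.pixels, fld.pixels)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(4)
        x = rng.normal(100, 20, (64, 64)).clip(0, 255)
        out = normalize_field(field_from(x)).pixels
        flat_in, flat_out = x.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)


class TestLabelProfiles:
    def test_uniform_image_labels_nothing(self):
        mask, thr = label_profiles(field_from(np.full((64, 64), 50, np.uint8)))
        assert not mask.any()

    def test_sparse_bright_pixels_labeled_exactly(self):
        """512×512 zeros with 100 pixels at 255: mean ≈ 0.097, SD ≈ 5.0,
        threshold ≈ 10.1, so the mask is exactly the 100 bright pixels."""
        x = np.zeros((512, 512), dtype=np.uint8)
        rng = np.random.default_rng(5)
        idx = rng.choice(512 * 512, size=100, replace=False)
        x.ravel()[idx] = 255
        mask, thr = label_profiles(field_from(x))
        p = 100 / 512**2
        expected_thr = 255 * p + 2 * 255 * np.sqrt(p * (1 - p))
        assert thr == pytest.approx(expected_thr, rel=1e-9)
        assert mask.sum() == 100
        assert np.all(x[mask] == 255)

    def test_recovers_synthetic_truth_mask(self):
        design = FieldDesign(image_size=(256, 256), background_sd=5.0,
                             signal_gain=150.0)
        fld = simulate_micrograph(design, seed=6)
        res_mask, _ = label_profiles(normalize_field(fld))
        truth = fld.truth_mask
        tp = (res_mask & truth).sum()
        precision = tp / max(res_mask.sum(), 1)
        recall = tp / truth.sum()
        assert recall >= 0.99
        assert precision >= 0.9

    def test_labeled_area_monotone_in_sd_multiplier(self):
        fld = simulate_micrograph(FieldDesign(image_size=(128, 128)), seed=7)
        work = normalize_field(fld)
        m2, _ = label_profiles(work, sd_multiplier=2.0)
        m3, _ = label_profiles(work, sd_multiplier=3.0)
        assert m3.sum() <= m2.sum()

    def test_threshold_drops_when_signal_removed(self):
        """Removing the signal pixels lowers mean + 2SD: the criterion points
        in the right direction."""
        fld = simulate_micrograph(FieldDesign(image_size=(128, 128)), seed=8)
        x = fld.pixels.astype(float)
        thr_full = x.mean() + 2 * x.std()
        bg = x[~fld.truth_mask]
        thr_bg = bg.mean() + 2 * bg.std()
        assert thr_bg <= thr_full


class TestMeasureField:
    def test_trivial_arithmetic(self):
        x = np.zeros((64, 64), dtype=np.uint8)
        mask = np.zeros_like(x, dtype=bool)
        mask.ravel()[:100] = True
        x[mask] = 255
        res = measure_field(field_from(x), mask)
        assert res.mean_gray == 255.0
        assert res.labeled_area_px == 100

    def test_empty_mask(self):
        x = np.full((64, 64), 9, dtype=np.uint8)
        res = measure_field(field_from(x), np.zeros_like(x, dtype=bool))
        assert res.mean_gray is None
        assert res.labeled_area_px == 0

    def test_equals_bruteforce_masked_mean(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        mask = rng.random((64, 64)) < 0.2
        res = measure_field(field_from(x), mask)
        total, count = 0.0, 0
        for i in range(64):
            for j in range(64):
                if mask[i, j]:
                    total += float(x[i, j])
                    count += 1
        assert res.labeled_area_px == count
        assert res.mean_gray == pytest.approx(total / count, abs=1e-12)

    def test_pixel_calibration(self):
        x = np.zeros((64, 64), dtype=np.uint8)
        mask = np.zeros_like(x, dtype=bool)
        mask[:2, :5] = True
        res = measure_field(field_from(x, pixel_size_um=0.5), mask)
        assert res.labeled_area_um2 == pytest.approx(10 * 0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            measure_field(field_from(np.zeros((64, 64))), np.zeros((32, 32), bool))


class TestAggregate:
    def test_single_subject_identical_fields_idempotent(self):
        design = FieldDesign(image_size=(128, 128))
        fld = simulate_micrograph(design, seed=10)
        fld.subject, fld.group = "y-01", "young"
        results = [quantify_field(fld) for _ in range(3)]
        agg = aggregate(results)
        assert len(agg["subjects"]) == 1
        assert agg["subjects"].loc[0, "labeled_area_px"] == results[0].labeled_area_px

    def test_condition_factor_ratio_recovered(self):
        """Groups with condition factors 1.0 vs 0.5 show a ≈2:1 ratio of
        group-mean labeled areas."""
        designs = {"young": FieldDesign(image_size=(128, 128), n_rings=4,
                                        n_puncta=40, condition_factor=1.0),
                   "old": FieldDesign(image_size=(128, 128), n_rings=4,
                                      n_puncta=40, condition_factor=0.5)}
        cohort = simulate_histology_cohort(designs, n_subjects=2,
                                           sections_per_subject=1, seed=11)
        agg = aggregate([quantify_field(f) for f in cohort.fields])
        g = agg["groups"].set_index("group")
        ratio = g.loc["young", "labeled_area_px_mean"] / g.loc["old", "labeled_area_px_mean"]
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_empty_input_gives_empty_tables(self):
        agg = aggregate([])
        assert agg["fields"].empty and agg["subjects"].empty and agg["groups"].empty
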