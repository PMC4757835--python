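import numpy as np
import pytest

from kinetex import dyntex, phantom
from kinetex.core import DceSeries, RoiMask, ValidationError
from kinetex.dyntex import (dhog_descriptor, dhog_features, dlbp_descriptor,
                            dlbp_features, lbp_codes, orientation_field)


def _series_from(frames):
    return DceSeries(np.asarray(frames, dtype=float),
                     np.arange(len(frames), dtype=float))


def _full_mask(h, w, margin=2):
    m = np.zeros((h, w), dtype=bool)
    m[margin:h - margin, margin:w - margin] = True
    return RoiMask(m)


class TestOrientationField:
    def test_constant_image_no_valid_pixels(self):
        roi = np.ones((10, 10), dtype=bool)
        fld = orientation_field(np.full((10, 10), 7.0), roi)
        assert fld.magnitude.max() == 0
        assert not fld.valid.any()

    def test_x_ramp_orientations_zero(self):
        img = np.tile(np.arange(12, dtype=float), (12, 1))
        roi = np.ones((12, 12), dtype=bool)
        fld = orientation_field(img, roi)
        assert fld.valid.all()
        np.testing.assert_allclose(fld.orientation[fld.valid], 0.0)

    def test_rotation_by_90_shifts_orientations(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(14, 14))
        roi = np.ones((14, 14), dtype=bool)
        base = orientation_field(img, roi)
        rot = orientation_field(np.rot90(img), roi)
        # rot90 shifts every gradient orientation by -90 degrees (the row
        # axis points down, so the screen-space rotation is clockwise)
        expect = (np.rot90(base.orientation) - 90.0) % 360.0
        both = np.rot90(base.valid) & rot.valid
        np.testing.assert_allclose(rot.orientation[both], expect[both],
                                   atol=1e-9)


class TestDhog:
    def test_count_conservation_per_phase(self, lesion):
        series, mask, _ = lesion
        L = 3
        desc = dhog_descriptor(series, mask, bins=8, levels=L)
        rs, cs = mask.bounding_box()
        roi = mask.mask[rs, cs]
        for ti in range(series.n_phases):
            fld = orientation_field(series.frames[ti][rs, cs], roi)
            assert desc.per_phase[ti].sum() == pytest.approx(
                fld.valid.sum() * L)

    def test_ramp_image_zero_entropy(self):
        img = np.tile(np.arange(16, dtype=float), (16, 1)) * 3
        series = _series_from([img + k for k in range(5)])
        mask = _full_mask(16, 16)
        for bins in (2, 4, 10):
            assert dhog_descriptor(series, mask, bins).scalar == 0.0

    def test_90_rotation_cyclically_shifts_histogram(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(50, 5, size=(5, 18, 18))
        series = _series_from(frames)
        rot = _series_from(np.stack([np.rot90(f) for f in frames]))
        mask = _full_mask(18, 18)
        h1 = dhog_descriptor(series, mask, 4).averaged
        h2 = dhog_descriptor(rot, mask, 4).averaged
        np.testing.assert_allclose(h2, np.roll(h1, -1), atol=1e-9)

    def test_five_features_and_determinism(self, lesion):
        series, mask, _ = lesion
        f1 = dhog_features(series, mask)
        f2 = dhog_features(series, mask)
        assert list(f1) == [f"dhog.b{b}" for b in (2, 4, 6, 8, 10)]
        assert f1 == f2

    def test_intensity_offset_and_scale_invariance(self, lesion):
        series, mask, _ = lesion
        other = DceSeries(series.frames * 3.0 + 40.0, series.times,
                          series.pixel_spacing)
        f1, f2 = dhog_features(series, mask), dhog_features(other, mask)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)

    def test_invalid_bins_rejected(self, lesion):
        series, mask, _ = lesion
        with pytest.raises(ValidationError):
            dhog_descriptor(series, mask, bins=0)


class TestLbpCodes:
    def test_constant_image_all_255(self):
        roi = np.ones((8, 8), dtype=bool)
        codes, valid = lbp_codes(np.full((8, 8), 3.0), roi)
        assert np.all(codes[valid] == 255)

    def test_hand_enumerated_patch(self):
        patch = np.array([[5, 4, 3], [2, 6, 1], [0, 9, 8]], dtype=float)
        roi = np.ones((3, 3), dtype=bool)
        codes, valid = lbp_codes(patch, roi)
        assert valid[1, 1]
        assert codes[1, 1] == 12

    def test_strict_peak_gives_zero(self):
        img = np.zeros((5, 5))
        img[2, 2] = 10.0
        roi = np.ones((5, 5), dtype=bool)
        codes, valid = lbp_codes(img, roi)
        assert codes[2, 2] == 0

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(11)
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                   (1, 1), (1, 0), (1, -1), (0, -1)]
        for _ in range(5):
            img = rng.integers(0, 30, size=(12, 12)).astype(float)
            roi = rng.random((12, 12)) < 0.8
            codes, valid = lbp_codes(img, roi)
            for r in range(1, 11):
                for c in range(1, 11):
                    if not roi[r, c]:
                        assert not valid[r, c]
                        continue
                    code = 0
                    for bit, (dr, dc) in enumerate(offsets):
                        if img[r + dr, c + dc] >= img[r, c]:
                            code |= 1 << (7 - bit)
                    assert codes[r, c] == code


class TestDlbp:
    def test_per_cell_histograms_sum_to_one(self, lesion):
        series, mask, _ = lesion
        desc = dlbp_descriptor(series, mask, 16)
        sums = desc.per_cell.sum(axis=1)
        nonempty = sums > 0
        np.testing.assert_allclose(sums[nonempty], 1.0, atol=1e-12)

    def test_constant_series_entropy_counts_cells(self):
        series = _series_from(np.full((5, 20, 20), 9.0))
        mask = _full_mask(20, 20)
        desc = dlbp_descriptor(series, mask, 256)
        n_nonempty = int((desc.per_cell.sum(axis=1) > 0).sum())
        assert desc.scalar == pytest.approx(np.log2(n_nonempty))
        # all mass sits in the all-ones code bin
        assert np.all(desc.per_cell[:, :255].sum(axis=1) == 0)

    def test_refinement_consistency(self, lesion):
        series, mask, _ = lesion
        h256 = dlbp_descriptor(series, mask, 256).per_cell
        h8 = dlbp_descriptor(series, mask, 8).per_cell
        np.testing.assert_allclose(h8, h256.reshape(h8.shape[0], 8, 32).sum(2),
                                   atol=1e-12)

    def test_six_features_and_offset_invariance(self, lesion):
        series, mask, _ = lesion
        f1 = dlbp_features(series, mask)
        assert list(f1) == [f"dlbp.b{b}" for b in (8, 16, 32, 64, 128, 256)]
        shifted = DceSeries(series.frames + 123.0, series.times,
                            series.pixel_spacing)
        f2 = dlbp_features(shifted, mask)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)

    def test_invalid_bins_rejected(self, lesion):
        series, mask, _ = lesion
        with pytest.raises(ValidationError):
            dlbp_descriptor(series, mask, 33)


class TestHeterogeneityResponse:
    """The dynamic descriptors track the planted heterogeneity dial.

    Under additive acquisition noise the homogeneous lesions' orientation
    and code histograms are noise-dominated and nearly uniform (maximal
    entropy); planted structure concentrates them, so the entropy scalars
    decrease monotonically as heterogeneity rises and the two classes
    separate.
    """

    @staticmethod
    def _class_scalars(het, n, key, noise_sd=2.0):
        acq = phantom.AcquisitionParams(noise_sd=noise_sd)
        vals = []
        for s in range(n):
            series, mask, _ = phantom.make_lesion(
                seed=1000 + s, radius_mm=5.5, spiculation=0.1,
                heterogeneity=het, mean_ktrans=0.17, ve=0.4, acq=acq)
            if key.startswith("dhog"):
                vals.append(dhog_features(series, mask)[key])
            else:
                vals.append(dlbp_features(series, mask)[key])
        return np.array(vals)

    def test_dhog_separates_heterogeneity_classes(self):
        from scipy.stats import mannwhitneyu
        lo = self._class_scalars(0.05, 20, "dhog.b4")
        hi = self._class_scalars(0.5, 20, "dhog.b4")
        assert mannwhitneyu(lo, hi).pvalue < 0.01

    def test_dlbp_separates_heterogeneity_classes(self):
        # LBP codes compare immediate neighbours, so the structure must be
        # resolvable above the noise floor: probed at 0.5% of S0 noise,
        # where the code histograms respond cleanly to the planted field
        from scipy.stats import mannwhitneyu
        lo = self._class_scalars(0.05, 20, "dlbp.b256", noise_sd=0.5)
        hi = self._class_scalars(0.5, 20, "dlbp.b256", noise_sd=0.5)
        assert mannwhitneyu(lo, hi).pvalue < 0.01

    def test_monotone_response_to_heterogeneity(self):
        dhog_means = [self._class_scalars(h, 10, "dhog.b4").mean()
                      for h in (0.05, 0.2, 0.5)]
        dlbp_means = [self._class_scalars(h, 10, "dlbp.b256",
                                          noise_sd=0.5).mean()
                      for h in (0.05, 0.2, 0.5)]
        assert dhog_means[0] > dhog_means[1] > dhog_means[2]
        assert dlbp_means[0] > dlbp_means[1] > dlbp_means[2]


class TestLbpHypothesis:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_codes_match_loop_oracle_on_random_patches(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 12, size=(6, 6)).astype(float)
        roi = np.ones((6, 6), dtype=bool)
        codes, valid = lbp_codes(img, roi)
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                   (1, 1), (1, 0), (1, -1), (0, -1)]
        for r in range(1, 5):
            for c in range(1, 5):
                code = 0
                for bit, (dr, dc) in enumerate(offsets):
                    if img[r + dr, c + dc] >= img[r, c]:
                        code |= 1 << (7 - bit)
                assert codes[r, c] == code
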