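"""Axial circular statistics, ROI placement and the comparison table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psoctpipe.enface import ParameterMapStack
from psoctpipe.roistats import (
    ROI,
    angular_difference,
    circ_mean_axial,
    extract_roi_table,
    pearson,
    place_rois,
    polar_histogram,
    wm_summary,
)


class TestCircMeanAxial:
    def test_identical_angles(self):
        assert circ_mean_axial([10.0, 10.0]) == pytest.approx(10.0, abs=1e-9)

    def test_axial_wraparound_170_and_10_average_to_zero(self):
        # doubling oracle: unit vectors at 340 and 20 deg average toward 0
        got = circ_mean_axial([170.0, 10.0])
        assert min(got, 180.0 - got) == pytest.approx(0.0, abs=1e-9)

    def test_balanced_input_is_degenerate(self):
        assert np.isnan(circ_mean_axial([0.0, 90.0]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            circ_mean_axial([])
        with pytest.raises(ValueError):
            circ_mean_axial([np.nan, np.nan])

    def test_weights_shift_the_mean(self):
        got = circ_mean_axial([0.0, 40.0], weights=[3.0, 1.0])
        assert 0.0 < got < 20.0

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 179.99), min_size=2, max_size=12),
        st.floats(0.0, 179.0),
    )
    def test_equivariant_under_global_rotation(self, angles, shift):
        base = circ_mean_axial(angles)
        rotated = circ_mean_axial([(a + shift) % 180.0 for a in angles])
        if np.isnan(base) or np.isnan(rotated):
            return  # degenerate resultant: no defined mean to compare
        d = abs((base + shift) % 180.0 - rotated)
        assert min(d, 180.0 - d) < 1e-6

    def test_invariant_under_per_sample_relabeling(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 180, 20)
        relabeled = np.where(rng.random(20) < 0.5, a, np.mod(a + 180.0, 180.0))
        assert circ_mean_axial(a) == pytest.approx(circ_mean_axial(relabeled))


class TestAngularDifference:
    def test_polar_space_worked_example(self):
        assert angular_difference(178.0, 1.0) == 3.0

    @pytest.mark.parametrize("theta", [0.0, 45.0, 90.0, 133.7])
    def test_zero_for_equal_angles(self, theta):
        assert angular_difference(theta, theta) == 0.0

    def test_maximum_is_90(self):
        assert angular_difference(0.0, 90.0) == 90.0

    def test_nan_propagates(self):
        assert np.isnan(angular_difference(np.nan, 10.0))

    def test_symmetry_bound_and_invariance_on_one_degree_grid(self):
        a = np.arange(180.0)
        b = np.arange(180.0)
        aa, bb = np.meshgrid(a, b, indexing="ij")
        d = angular_difference(aa, bb)
        assert np.array_equal(d, angular_difference(bb, aa))
        assert d.min() >= 0.0 and d.max() <= 90.0
        assert np.array_equal(d, angular_difference(aa + 180.0, bb))
        assert np.array_equal(d, angular_difference(aa, bb + 180.0))

    def test_triangle_inequality_on_half_circle_metric(self):
        g = np.arange(0.0, 180.0, 3.0)
        dab = angular_difference(g[:, None, None], g[None, :, None])
        dbc = angular_difference(g[None, :, None], g[None, None, :])
        dac = angular_difference(g[:, None, None], g[None, None, :])
        assert np.all(dac <= dab + dbc + 1e-9)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0])
        # direct product-moment formula as the oracle
        expected = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert pearson(x, y) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(np.sqrt(3) / 2, rel=1e-12)

    def test_pairwise_nan_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 100.0, 8.0, np.nan])
        assert pearson(x, y) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestPlaceRois:
    def test_full_mask_returns_complete_lattice(self):
        mask = np.ones((90, 60), bool)
        rois = place_rois(mask, roi_size_um=300.0, pixel_um=10.0)
        assert len(rois) == 3 * 2
        assert len({(r.y0, r.x0) for r in rois}) == 6

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            place_rois(np.zeros((60, 60), bool), roi_size_um=300.0, pixel_um=10.0)

    def test_requested_count_is_exact_and_distinct(self):
        mask = np.ones((450, 450), bool)
        rois = place_rois(mask, roi_size_um=300.0, pixel_um=10.0, n_rois=120, seed=0)
        assert len(rois) == 120
        assert len({(r.y0, r.x0) for r in rois}) == 120

    def test_wm_fraction_filter(self):
        mask = np.zeros((90, 90), bool)
        mask[0:30, :] = True  # only the first lattice row is pure WM
        rois = place_rois(mask, roi_size_um=300.0, pixel_um=10.0, min_wm_frac=0.8)
        assert all(r.y0 == 0 for r in rois)


class TestExtractRoiTable:
    def _stack(self, mu, ret, theta):
        return ParameterMapStack(
            mu_s_map=mu, retardance_map=ret, orientation_map=theta, pixel_um=10.0
        )

    def test_constant_maps_reported_exactly(self):
        shape = (60, 60)
        st_ = self._stack(np.full(shape, 4.0), np.full(shape, 20.0),
                          np.full(shape, 37.0))
        dmri = {"adc": np.full(shape, 8e-4), "fa": np.full(shape, 0.5),
                "theta": np.full(shape, 35.0)}
        rois = [ROI(0, 0, 30), ROI(30, 30, 30)]
        tab = extract_roi_table(st_, dmri, rois)
        assert len(tab) == 2
        assert np.allclose(tab["mean_mu_s"], 4.0)
        assert np.allclose(tab["circ_mean_theta_psoct"], 37.0)
        assert np.allclose(tab["circ_mean_theta_dmri"], 35.0)

    def test_all_nan_roi_dropped_with_warning(self):
        shape = (60, 60)
        mu = np.full(shape, 2.0)
        mu[0:30, 0:30] = np.nan
        st_ = self._stack(mu, np.full(shape, 10.0), np.full(shape, 10.0))
        dmri = {"adc": mu, "fa": mu, "theta": mu}
        with pytest.warns(UserWarning):
            tab = extract_roi_table(st_, dmri, [ROI(0, 0, 30), ROI(30, 30, 30)])
        assert len(tab) == 1

    def test_grid_mismatch_rejected(self):
        st_ = self._stack(np.zeros((10, 10)), np.zeros((10, 10)), np.zeros((10, 10)))
        dmri = {"adc": np.zeros((8, 8)), "fa": np.zeros((8, 8)),
                "theta": np.zeros((8, 8))}
        with pytest.raises(ValueError):
            extract_roi_table(st_, dmri, [ROI(0, 0, 5)])


class TestWmSummary:
    def test_constant_map(self):
        assert wm_summary(np.full((5, 5), 3.0), np.ones((5, 5), bool)) == (3.0, 0.0)

    def test_two_pixel_hand_case(self):
        m = np.array([[1.0, 3.0], [99.0, 99.0]])
        mask = np.array([[True, True], [False, False]])
        mean, sd = wm_summary(m, mask, ddof=0)
        assert (mean, sd) == (2.0, 1.0)

    def test_nans_outside_mask_ignored(self):
        m = np.array([[1.0, 3.0], [np.nan, np.nan]])
        mask = np.array([[True, True], [False, False]])
        assert wm_summary(m, mask) == (2.0, 1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            wm_summary(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestPolarHistogram:
    def test_all_zero_differences_fill_first_bin(self):
        counts, edges = polar_histogram(np.zeros(25), bin_deg=10.0)
        assert counts[0] == 25 and counts[1:].sum() == 0

    def test_counts_conserve_n(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 90, 137)
        counts, _ = polar_histogram(d, bin_deg=15.0)
        assert counts.sum() == 137

    def test_uniform_bin_centers_give_equal_counts(self):
        centers = np.arange(5.0, 90.0, 10.0)
        counts, _ = polar_histogram(np.tile(centers, 4), bin_deg=10.0)
        assert np.all(counts == 4)

    def test_plot_artifact_written(self, tmp_path):
        out = tmp_path / "polar.png"
        polar_histogram(np.array([3.0, 50.0]), bin_deg=30.0, plot_path=str(out))
        assert out.exists() and out.stat().st_size > 0
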