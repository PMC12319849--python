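"""Registration recovery, Dice, vector reorientation, mask construction."""

import numpy as np
import pytest
from scipy import ndimage

from psoctpipe.coreg import (
    AffineTransform,
    dice,
    make_masks,
    register_affine,
    reorient_and_project,
    resample,
)


def _smooth_map(shape=(120, 120), seed=0):
    """Band-limited synthetic mu_s-like map: bright WM blob on dim tissue."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=shape)
    base = ndimage.gaussian_filter(base, 6.0)
    yy, xx = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    tissue = (np.hypot(yy - cy, xx - cx) < shape[0] * 0.42).astype(float)
    wm = ((np.abs(yy - cy) < shape[0] * 0.14)
          | (np.abs(xx - cx) < shape[0] * 0.14)).astype(float) * tissue
    return 0.3 + tissue * 1.0 + wm * 3.0 + 0.15 * base * tissue


def _apply_known_transform(fixed, a_true, t_true):
    """moving(q) = fixed(A_true q + t_true) by pull-back resampling."""
    inv = np.linalg.inv(a_true)
    tr = AffineTransform(matrix=inv, translation=-inv @ t_true)
    mov = resample(fixed, tr, fixed.shape, interpolation="linear")
    return np.nan_to_num(mov, nan=float(np.nanmedian(mov)))


class TestDice:
    def test_unit_cases(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        b = np.zeros((10, 10), bool)
        b[5:] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0

    def test_half_overlap_is_half(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:5, 0:20] = True  # 100 px
        b[0:5, 10:20] = True
        b[5:10, 0:10] = True  # 100 px, 50 shared
        assert dice(a, b) == 0.5

    def test_symmetric_and_empty_convention(self):
        rng = np.random.default_rng(2)
        a = rng.random((15, 15)) > 0.5
        b = rng.random((15, 15)) > 0.5
        assert dice(a, b) == dice(b, a)
        empty = np.zeros((5, 5), bool)
        assert dice(empty, empty) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestPolarDecomposition:
    def test_pure_rotation_is_its_own_rotational_component(self):
        r = np.deg2rad(25.0)
        rot = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        t = AffineTransform(matrix=rot, translation=[0, 0])
        assert np.allclose(t.rotational_component, rot, atol=1e-12)
        assert t.rotation_deg == pytest.approx(25.0, abs=1e-9)

    def test_pure_anisotropic_scaling_gives_identity_rotation(self):
        t = AffineTransform(matrix=np.diag([2.0, 0.5]), translation=[1, 2])
        assert np.allclose(t.rotational_component, np.eye(2), atol=1e-12)

    def test_rotation_times_scale_recovers_rotation(self):
        r = np.deg2rad(-12.0)
        rot = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        t = AffineTransform(matrix=rot @ np.diag([1.1, 0.93]), translation=[0, 0])
        assert t.rotation_deg == pytest.approx(-12.0, abs=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(matrix=[[1.0, 2.0], [2.0, 4.0]], translation=[0, 0])


class TestResample:
    def test_identity(self):
        img = _smooth_map((40, 40))
        t = AffineTransform(matrix=np.eye(2), translation=[0, 0])
        out = resample(img, t, img.shape)
        assert np.allclose(out, img, atol=1e-9)

    def test_integer_translation_nearest_is_a_shift(self):
        img = np.arange(36.0).reshape(6, 6)
        t = AffineTransform(matrix=np.eye(2), translation=[2, 1])  # (dx, dy)
        out = resample(img, t, img.shape, interpolation="nearest")
        assert np.array_equal(out[1:, 2:], img[:-1, :-2])

    def test_round_trip_on_band_limited_map(self):
        rng = np.random.default_rng(3)
        img = ndimage.gaussian_filter(rng.normal(size=(60, 60)), 4.0) * 10.0
        r = np.deg2rad(9.0)
        a = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        t = AffineTransform(matrix=a, translation=[1.5, -2.0])
        fwd = resample(img, t, (60, 60))
        back = resample(np.nan_to_num(fwd), t.inverse(), (60, 60))
        core = np.s_[15:45, 15:45]
        assert np.nanmax(np.abs(back[core] - img[core])) < 0.05


class TestRegisterAffine:
    def test_self_registration_is_identity(self):
        img = _smooth_map((80, 80))
        t = register_affine(img, img, 10.0, 10.0, levels=2, invert_moving=False)
        assert abs(t.rotation_deg) < 1e-3
        assert np.abs(t.translation).max() < 1e-3
        assert np.allclose(t.matrix, np.eye(2), atol=1e-3)

    def test_known_rotation_and_shift_recovered(self):
        fixed = _smooth_map((120, 120))
        r = np.deg2rad(7.0)
        a_true = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        t_true = np.array([3.0, -2.0])
        moving = _apply_known_transform(fixed, a_true, t_true)
        got = register_affine(fixed, moving, 10.0, 10.0, levels=3,
                              invert_moving=False)
        assert got.rotation_deg == pytest.approx(7.0, abs=0.5)
        assert np.abs(got.translation - t_true).max() < 0.5

    def test_constant_and_nonfinite_inputs_rejected(self):
        img = _smooth_map((40, 40))
        with pytest.raises(ValueError):
            register_affine(img, np.zeros_like(img), 10.0, 10.0)
        bad = img.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            register_affine(img, bad, 10.0, 10.0)


class TestReorientAndProject:
    def test_identity_rotation_cardinal_cases(self):
        t = AffineTransform(matrix=np.eye(2), translation=[0, 0])
        vecs = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        angles, ok = reorient_and_project(vecs, t)
        assert angles[0] == pytest.approx(0.0)
        assert angles[1] == pytest.approx(90.0)
        assert not ok[2] and np.isnan(angles[2])

    def test_rotation_shifts_in_plane_angle(self):
        r = np.deg2rad(30.0)
        rot = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
        t = AffineTransform(matrix=rot @ np.diag([1.05, 0.97]), translation=[0, 0])
        for base in (0.0, 40.0, 160.0):
            v = np.array([np.cos(np.deg2rad(base)), np.sin(np.deg2rad(base)), 0.0])
            angles, _ = reorient_and_project(v[None, :], t)
            assert angles[0] == pytest.approx((base + 30.0) % 180.0, abs=1e-6)

    def test_through_plane_threshold(self):
        t = AffineTransform(matrix=np.eye(2), translation=[0, 0])
        tilted = np.array([[0.05, 0.0, np.sqrt(1 - 0.05 ** 2)]])
        angles, ok = reorient_and_project(tilted, t, min_inplane=0.1)
        assert not ok[0]


def _otsu_oracle(values, nbins=256):
    """Exhaustive between-class-variance maximization over histogram bins."""
    hist, edges = np.histogram(values, bins=nbins)
    best, best_t = -1.0, edges[1]
    centers = (edges[:-1] + edges[1:]) / 2
    for k in range(1, nbins):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, edges[k]
    return best_t


class TestMakeMasks:
    def test_bimodal_threshold_splits_at_valley_within_one_bin(self):
        from psoctpipe.coreg import otsu_threshold

        rng = np.random.default_rng(8)
        values = np.concatenate([
            rng.normal(1.0, 0.4, 3000), rng.normal(3.0, 0.5, 2000)
        ])
        bin_w = np.ptp(values) / 256
        assert abs(otsu_threshold(values) - _otsu_oracle(values)) <= bin_w

    def test_flat_map_rejected(self):
        with pytest.raises(ValueError):
            make_masks(np.ones((10, 10)))

    def test_idempotent_under_remasking(self):
        img = _smooth_map((60, 60))
        m1 = make_masks(img)["tissue"]
        remasked = np.where(m1, img, img[~m1].min())
        m2 = make_masks(remasked)["tissue"]
        assert dice(m1, m2) > 0.98

    def test_wm_map_routes_second_threshold(self):
        adc = np.full((40, 40), 2.0e-3)
        adc[5:35, 5:35] = 0.9e-3
        fa = np.zeros((40, 40))
        fa[10:30, 10:30] = 0.6
        masks = make_masks(adc, invert=True, wm_map=fa, wm_value=0.2)
        assert masks["tissue"][5:35, 5:35].all() and not masks["tissue"][0:4].any()
        assert masks["wm"][10:30, 10:30].all()
        assert masks["wm"].sum() == 400

    def test_fixed_threshold_method(self):
        img = np.linspace(0, 1, 100).reshape(10, 10)
        masks = make_masks(img, method="threshold", value=0.5)
        assert masks["tissue"].sum() == 50
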