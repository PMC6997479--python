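"""Split renal function estimators: AUC, Rutland-Patlak, volumetric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renoquant.exceptions import (FitError, InputError, ParameterError,
                                  UndefinedSRFError)
from renoquant.phantom import PhantomSpec, renal_curve
from renoquant.srf import (PatlakFit, auc_srf, patlak_fit, patlak_srf,
                           segment_volume, volumetric_srf)

from conftest import add_noise, make_curve

WINDOW = (60.0, 160.0)


def make_fit(slope, intercept=0.0):
    return PatlakFit(slope_K=slope, intercept_V0=intercept, r_squared=1.0,
                     window=WINDOW, n_points=10)


class TestAucSrf:
    def test_identical_curves_split_evenly(self, mru_aorta):
        assert auc_srf(mru_aorta, mru_aorta, WINDOW) == (50.0, 50.0)

    def test_nonfunctioning_right_kidney(self, mru_aorta):
        zero = mru_aorta.with_values(np.zeros(mru_aorta.n_frames))
        assert auc_srf(mru_aorta, zero, WINDOW) == (100.0, 0.0)

    def test_two_to_one_ratio_matches_dense_oracle(self, default_spec,
                                                   mru_aorta, mru_schedule):
        """A kidney with twice the other's curve gets 2/3 of function; the
        trapezoid result agrees with a 1000x finer Riemann sum."""
        left = renal_curve(default_spec, "left", mru_aorta, mru_schedule)
        right = left.with_values(0.5 * left.values)
        s_l, s_r = auc_srf(left, right, WINDOW)

        # dense Riemann oracle on the linear interpolant
        t = np.linspace(*WINDOW, 1000 * 21)
        a_l = np.trapezoid(np.interp(t, left.times, left.values), t)
        a_r = np.trapezoid(np.interp(t, right.times, right.values), t)
        oracle = 100.0 * a_l / (a_l + a_r)
        assert abs(s_l - 200.0 / 3.0) < 1e-9
        assert abs(s_l - oracle) < 0.05
        assert s_l + s_r == 100.0

    def test_zero_pair_is_undefined(self, mru_aorta):
        zero = mru_aorta.with_values(np.zeros(mru_aorta.n_frames))
        with pytest.raises(UndefinedSRFError):
            auc_srf(zero, zero, WINDOW)

    def test_common_rescaling_invariance(self, default_spec, mru_aorta,
                                         mru_schedule):
        left = renal_curve(default_spec, "left", mru_aorta, mru_schedule)
        right = left.with_values(0.7 * left.values)
        base = auc_srf(left, right, WINDOW)
        scaled = auc_srf(left.with_values(13.0 * left.values),
                         right.with_values(13.0 * right.values), WINDOW)
        assert np.allclose(base, scaled)


class TestPatlakFit:
    def test_three_point_exact_line(self):
        """x = [1,2,3], y = [2,4,6] -> slope 2, intercept 0, r^2 = 1."""
        aorta = make_curve([0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])
        renal = make_curve([0, 1, 2, 3], [0.0, 2.0, 4.0, 6.0])
        fit = patlak_fit(renal, aorta, window=(1.0, 3.0))
        assert fit.n_points == 3
        assert abs(fit.slope_K - 2.0) < 1e-12
        assert abs(fit.intercept_V0) < 1e-12
        assert fit.r_squared == 1.0

    def test_generative_round_trip(self, mru_schedule):
        """Noise-free forward-model curve with K = 0.004, V_b = 0.1 is
        recovered within 1% (slope) and 5% (intercept)."""
        from renoquant.phantom import aortic_input

        spec = PhantomSpec(patlak_slope_left=0.004, blood_volume_fraction=0.1)
        aorta = aortic_input(mru_schedule, **spec.aortic_params())
        renal = renal_curve(spec, "left", aorta, mru_schedule)
        fit = patlak_fit(renal, aorta, WINDOW)
        assert abs(fit.slope_K - 0.004) / 0.004 < 0.01
        assert abs(fit.intercept_V0 - 0.1) / 0.1 < 0.05
        assert fit.r_squared > 0.999

    def test_pure_vascular_roi(self, mru_aorta):
        renal = mru_aorta.with_values(0.37 * mru_aorta.values)
        fit = patlak_fit(renal, mru_aorta, WINDOW)
        assert abs(fit.slope_K) < 1e-10
        assert abs(fit.intercept_V0 - 0.37) < 1e-10

    def test_matches_brute_force_least_squares(self, default_spec, mru_aorta,
                                               mru_schedule):
        """OLS result equals the explicit normal-equation solution."""
        renal = renal_curve(default_spec, "left", mru_aorta, mru_schedule)
        fit = patlak_fit(renal, mru_aorta, WINDOW)

        from scipy.integrate import cumulative_trapezoid
        t = renal.times
        cum = cumulative_trapezoid(mru_aorta.values, t, initial=0.0)
        sel = (t >= WINDOW[0]) & (t <= WINDOW[1])
        x = cum[sel] / mru_aorta.values[sel]
        y = renal.values[sel] / mru_aorta.values[sel]
        n = len(x)
        slope = (n * (x * y).sum() - x.sum() * y.sum()) \
            / (n * (x * x).sum() - x.sum() ** 2)
        intercept = (y.sum() - slope * x.sum()) / n
        assert abs(fit.slope_K - slope) < 1e-9 * abs(slope)
        assert abs(fit.intercept_V0 - intercept) < 1e-9

    def test_too_few_frames_is_fit_error(self, mru_aorta):
        with pytest.raises(FitError):
            patlak_fit(mru_aorta, mru_aorta, window=(60.0, 66.0))

    def test_nonpositive_input_frames_dropped(self):
        aorta = make_curve([0, 1, 2, 3, 4, 5], [1, 1, 0.0, 1, 1, 1])
        renal = make_curve([0, 1, 2, 3, 4, 5], [0, 1, 2, 3, 4, 5.0])
        with pytest.warns(UserWarning, match="non-positive"):
            fit = patlak_fit(renal, aorta, window=(0.0, 5.0))
        assert fit.n_points == 5


class TestPatlakSrf:
    def test_equal_slopes(self):
        assert patlak_srf(make_fit(0.004), make_fit(0.004)) == (50.0, 50.0)

    def test_three_to_one(self):
        assert patlak_srf(make_fit(0.006), make_fit(0.002)) == (75.0, 25.0)

    def test_negative_slope_floored(self):
        with pytest.warns(UserWarning, match="floored"):
            s = patlak_srf(make_fit(-0.001), make_fit(0.004))
        assert s == (0.0, 100.0)

    def test_noisy_phantom_recovery_65_35(self, mru_schedule):
        """Mean recovered left SRF over 20 noise seeds at 1% peak noise is
        within 2 points of the true 65%."""
        from renoquant.phantom import aortic_input

        spec = PhantomSpec.from_srf(65.0)
        aorta = aortic_input(mru_schedule, **spec.aortic_params())
        curves = {s: renal_curve(spec, s, aorta, mru_schedule)
                  for s in ("left", "right")}
        estimates = []
        for seed in range(20):
            fits = {s: patlak_fit(add_noise(curves[s], 0.01, seed + 31 * i),
                                  aorta, WINDOW)
                    for i, s in enumerate(("left", "right"))}
            estimates.append(patlak_srf(fits["left"], fits["right"])[0])
        assert abs(np.mean(estimates) - 65.0) < 2.0


class TestSegmentVolume:
    def _ellipsoid(self, shape, center, semi, voxel=2.0):
        idx = np.indices(shape).astype(float)
        coords = [(idx[i] - center[i]) * voxel for i in range(3)]
        return ((coords[0] / semi[0]) ** 2 + (coords[1] / semi[1]) ** 2
                + (coords[2] / semi[2]) ** 2) <= 1.0

    def test_phantom_ellipsoid_volume_recovered(self):
        """120 mL ellipsoid pair on a 2 mm grid, threshold 0.5, no noise:
        volumes within 3%."""
        semi = (3.0 * 120_000.0 / (8.0 * np.pi)) ** (1 / 3)
        semi_axes = (semi, semi, 2 * semi)
        frame = np.zeros((96, 48, 80))
        frame[self._ellipsoid((96, 48, 80), (70, 24, 40), semi_axes)] = 1.0
        frame[self._ellipsoid((96, 48, 80), (26, 24, 40), semi_axes)] = 1.0
        res = segment_volume(frame, 0.5, voxel_volume=8.0)
        assert res.n_components == 2
        assert abs(res.volume_left - 120.0) / 120.0 < 0.03
        assert abs(res.volume_right - 120.0) / 120.0 < 0.03
        # symmetric phantom: equal volumes to within one voxel
        assert abs(res.volume_left - res.volume_right) <= 8.0 / 1000.0

    def test_empty_frame_rejected(self):
        with pytest.raises(InputError):
            segment_volume(np.zeros((4, 4, 4)), 0.5)

    def test_single_component_reports_missing_side(self):
        frame = np.zeros((20, 10, 10))
        frame[14:18, 4:7, 4:7] = 1.0
        res = segment_volume(frame, 0.5, voxel_volume=8.0)
        assert res.volume_left is not None and res.volume_right is None

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            segment_volume(np.ones((3, 3, 3)), 1.5)


class TestVolumetricSrf:
    def test_equal_everything(self):
        assert volumetric_srf(0.004, 0.004, 100.0, 100.0) == (50.0, 50.0)

    def test_volume_proportional(self):
        s = volumetric_srf(0.004, 0.004, 120.0, 60.0)
        assert abs(s[0] - 200.0 / 3.0) < 1e-9

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ParameterError):
            volumetric_srf(0.004, 0.004, 0.0, 100.0)

    @given(k_l=st.floats(1e-4, 1e-2), k_r=st.floats(1e-4, 1e-2),
           v_l=st.floats(20.0, 300.0), v_r=st.floats(20.0, 300.0))
    @settings(max_examples=50, deadline=None)
    def test_pairs_sum_to_100(self, k_l, k_r, v_l, v_r):
        s_l, s_r = volumetric_srf(k_l, k_r, v_l, v_r)
        assert abs(s_l + s_r - 100.0) < 1e-9
        assert 0.0 <= s_l <= 100.0
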