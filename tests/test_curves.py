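"""Curve extraction, background correction, resampling and peak finding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renoquant.curves import (RegionMask, background_subtract, extract_curve,
                              find_peak, resample_uniform, smooth)
from renoquant.exceptions import InputError, ParameterError
from renoquant.phantom import (AcquisitionSchedule, PhantomSpec, aortic_input,
                               renal_curve)

from conftest import add_noise, make_curve


class TestExtractCurve:
    def schedule(self, n):
        return AcquisitionSchedule(5.0 * np.arange(n), np.full(n, 5.0), "mru")

    def test_constant_series_gives_constant_curve(self):
        frames = np.full((4, 5, 5), 3.25)
        mask = RegionMask("left_kidney", np.ones((5, 5), dtype=bool))
        curve = extract_curve(frames, mask, self.schedule(4), modality="mru")
        assert np.allclose(curve.values, 3.25)

    def test_single_element_mask_is_identity(self):
        rng = np.random.default_rng(0)
        frames = rng.random((6, 4, 4))
        m = np.zeros((4, 4), dtype=bool)
        m[2, 1] = True
        curve = extract_curve(frames, RegionMask("aorta", m),
                              self.schedule(6), modality="mru")
        assert np.allclose(curve.values, frames[:, 2, 1])

    @pytest.mark.parametrize("modality,expected", [
        ("mru", [1.5, 3.5, 5.5]),   # mean of the two voxels
        ("drs", [3.0, 7.0, 11.0]),  # sum of the two voxels
    ])
    def test_two_voxel_statistic(self, modality, expected):
        frames = np.zeros((3, 2, 2))
        frames[:, 0, 0] = [1, 3, 5]
        frames[:, 1, 1] = [2, 4, 6]
        m = np.zeros((2, 2), dtype=bool)
        m[0, 0] = m[1, 1] = True
        curve = extract_curve(frames, RegionMask("left_kidney", m),
                              self.schedule(3), modality=modality)
        assert np.allclose(curve.values, expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            RegionMask("left_kidney", np.zeros((3, 3), dtype=bool))

    def test_extract_then_subtract_is_linear(self):
        """The extract -> background-subtract composition is linear in the
        series values (before clipping bites)."""
        rng = np.random.default_rng(1)
        frames_a = rng.random((5, 3, 3))
        frames_b = rng.random((5, 3, 3))
        # kidney voxel dominates the background voxel in every frame so
        # that clipping never triggers for positive combinations
        frames_a[:, 0, 0] = frames_a[:, 2, 2] + 1.0
        frames_b[:, 0, 0] = frames_b[:, 2, 2] + 1.0
        mk = np.zeros((3, 3), dtype=bool)
        mk[0, 0] = True
        mb = np.zeros((3, 3), dtype=bool)
        mb[2, 2] = True
        sched = self.schedule(5)

        def pipeline(frames):
            k = extract_curve(frames, RegionMask("left_kidney", mk), sched,
                              modality="mru")
            b = extract_curve(frames, RegionMask("background", mb), sched,
                              modality="mru")
            return background_subtract(k, b).values

        combo = pipeline(2.0 * frames_a + 3.0 * frames_b)
        parts = 2.0 * pipeline(frames_a) + 3.0 * pipeline(frames_b)
        # clipping never triggers here because kidney >= 1 > background
        assert np.allclose(combo, parts)


class TestBackgroundSubtract:
    def test_zero_background_is_identity(self):
        k = make_curve([0, 5, 10], [3.0, 4.0, 5.0])
        b = k.with_values(np.zeros(3))
        out = background_subtract(k, b)
        assert np.allclose(out.values, k.values)
        assert out.flags["clipped_frames"] == 0

    def test_perfect_cancellation(self):
        k = make_curve([0, 5, 10], [3.0, 4.0, 5.0], modality="drs")
        out = background_subtract(k, k, size_ratio=1.0)
        assert np.allclose(out.values, 0.0)

    def test_hand_arithmetic_with_size_ratio(self):
        k = make_curve([0, 5], [10.0, 20.0], modality="drs")
        b = make_curve([0, 5], [2.0, 4.0], modality="drs")
        out = background_subtract(k, b, size_ratio=2.0)
        assert np.allclose(out.values, [6.0, 12.0])

    def test_schedule_mismatch_rejected(self):
        k = make_curve([0, 5, 10], [1, 2, 3])
        b = make_curve([0, 5], [1, 2])
        with pytest.raises(InputError):
            background_subtract(k, b)

    def test_drs_requires_size_ratio(self):
        k = make_curve([0, 5], [1, 2], modality="drs")
        with pytest.raises(InputError):
            background_subtract(k, k)

    def test_negatives_clipped_and_counted(self):
        k = make_curve([0, 5, 10], [5.0, 1.0, 5.0])
        b = make_curve([0, 5, 10], [1.0, 2.0, 1.0])
        out = background_subtract(k, b, size_ratio=2.0)
        assert np.allclose(out.values, [3.0, 0.0, 3.0])
        assert out.flags["clipped_frames"] == 1


class TestResampleUniform:
    def test_idempotent_on_uniform_grid(self):
        c = make_curve(2.5 + 5.0 * np.arange(10), np.arange(10.0) ** 2)
        out = resample_uniform(c, 5.0)
        assert np.allclose(out.times, c.times)
        assert np.allclose(out.values, c.values)

    def test_linear_ramp_exact_at_any_dt(self):
        c = make_curve([0.0, 10.0, 30.0, 60.0], [0.0, 20.0, 60.0, 120.0])
        out = resample_uniform(c, 7.0)
        assert np.allclose(out.values, 2.0 * out.times)
        assert out.times[0] == c.start and out.times[-1] == c.end

    def test_dual_rate_phantom_integral_preserved(self, mru_aorta,
                                                  default_spec, mru_schedule):
        c = renal_curve(default_spec, "left", mru_aorta, mru_schedule)
        out = resample_uniform(c, 5.0)
        before = np.trapezoid(c.values, c.times)
        after = np.trapezoid(out.values, out.times)
        assert abs(after - before) / before < 0.01

    def test_no_overshoot(self):
        c = make_curve([0, 5, 10, 15], [0.0, 10.0, 2.0, 8.0])
        out = resample_uniform(c, 1.5)
        assert out.values.min() >= c.values.min() - 1e-12
        assert out.values.max() <= c.values.max() + 1e-12

    def test_too_short_curve_rejected(self):
        c = make_curve([0.0], [1.0])
        with pytest.raises(InputError):
            resample_uniform(c, 1.0)


class TestFindPeak:
    def test_monotone_curve_peaks_at_last_frame(self):
        c = make_curve(np.arange(10.0), np.arange(10.0))
        assert find_peak(c, 3).t_peak == c.end

    def test_triangle_apex(self):
        values = np.concatenate([np.arange(6.0), np.arange(4.0, -1.0, -1)])
        c = make_curve(np.arange(11.0) * 5, values)
        assert find_peak(c, 1).t_peak == 25.0

    def test_flat_curve_flagged(self):
        c = make_curve(np.arange(5.0), np.full(5, 2.0))
        res = find_peak(c)
        assert res.flat and res.t_peak == c.start

    def test_even_window_rejected(self):
        c = make_curve(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ParameterError):
            find_peak(c, smooth_window=4)

    @given(scale=st.floats(0.1, 100.0), offset=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(42)
        c = make_curve(np.arange(20.0) * 5, rng.random(20))
        assert (find_peak(c, 5).t_peak
                == find_peak(c.with_values(scale * c.values + offset), 5).t_peak)

    def test_noisy_phantom_peak_recovery(self, mru_aorta, default_spec,
                                         mru_schedule):
        """At 2% noise the smoothed peak lands within 10 s of the
        noise-free peak in at least 95 of 100 replicates."""
        c = renal_curve(default_spec, "left", mru_aorta, mru_schedule)
        t0 = c.times[np.argmax(smooth(c.values, 5))]
        hits = sum(abs(find_peak(add_noise(c, 0.02, seed), 5).t_peak - t0) <= 10.0
                   for seed in range(100))
        assert hits >= 95
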