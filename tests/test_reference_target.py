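import numpy as np
import pytest
from hypothesis import given, strategies as st

import ppgcond as pc
from ppgcond.reference_target import bottom_flatten


class TestWindowPeriods:
    def test_equal_periods(self):
        ann = pc.PeakAnnotation(
            np.array([3.4, 4.2, 5.0, 25.0, 25.8, 26.6]), 5.5, 24.5
        )
        T_A, T_B, T_M = pc.window_periods(ann)
        assert (T_A, T_B, T_M) == pytest.approx((0.8, 0.8, 0.8))

    def test_mean_of_unequal_periods(self):
        ann = pc.PeakAnnotation(
            np.array([4.0, 4.75, 25.0, 25.85]), 5.0, 24.5
        )
        T_A, T_B, T_M = pc.window_periods(ann)
        assert (T_A, T_B, T_M) == pytest.approx((0.75, 0.85, 0.80))

    def test_single_peak_in_window_errors(self):
        ann = pc.PeakAnnotation(np.array([4.0, 25.0, 25.8]), 5.0, 24.5)
        with pytest.raises(ValueError, match="Window A"):
            pc.window_periods(ann)


class TestCheckGap:
    @pytest.mark.parametrize(
        "t_A,t_B,T_M,exp_n,exp_round",
        [(5.0, 13.0, 0.8, 10.0, 10), (5.0, 13.0, 1.0, 8.0, 8)],
    )
    def test_exact_multiples(self, t_A, t_B, T_M, exp_n, exp_round):
        n, n_round, valid = pc.check_gap(t_A, t_B, T_M)
        assert n == pytest.approx(exp_n)
        assert n_round == exp_round
        assert valid

    def test_half_boundary_counts_as_valid(self):
        # n = 9.5 rounds half-up to 10; |9.5 - 10| = 0.5 <= 0.5
        n, n_round, valid = pc.check_gap(0.0, 9.5, 1.0)
        assert n == pytest.approx(9.5)
        assert n_round == 10
        assert valid

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            pc.check_gap(5.0, 13.0, 0.0)
        with pytest.raises(ValueError):
            pc.check_gap(5.0, 5.0, 1.0)


class TestInterpolateIntervals:
    def test_constant_rate_case(self):
        T = pc.interpolate_intervals(0.8, 5.0, 13.0, 10)
        assert np.allclose(T, 0.8)
        inserted = 5.0 + np.cumsum(T)[:-1]
        assert len(inserted) == 9

    def test_ramp_case_matches_closed_form(self):
        T = pc.interpolate_intervals(0.6, 5.0, 13.0, 10)
        i = np.arange(1, 11)
        assert np.allclose(T, 0.6 + 0.4 * i / 11)
        assert np.sum(T) == pytest.approx(8.0, abs=1e-12)

    @given(
        T_A=st.floats(0.4, 1.4),
        T_B=st.floats(0.4, 1.4),
        t_A=st.floats(2.0, 8.0),
        gap=st.floats(2.0, 25.0),
    )
    def test_conservation_and_linearity(self, T_A, T_B, t_A, gap):
        """Sum of intervals is exactly the gap; the ramp is linear in i."""
        t_B = t_A + gap
        T_M = 0.5 * (T_A + T_B)
        _, n_round, _ = pc.check_gap(t_A, t_B, T_M)
        T = pc.interpolate_intervals(T_A, t_A, t_B, n_round)
        assert abs(np.sum(T) - gap) < 1e-9
        assert np.mean(T) == pytest.approx(gap / n_round)
        if len(T) > 2:
            assert np.max(np.abs(np.diff(T, 2))) < 1e-9

    def test_invalid_n_round(self):
        with pytest.raises(ValueError):
            pc.interpolate_intervals(0.8, 5.0, 13.0, 0)


class TestBottomFlatten:
    def test_worked_values(self):
        assert bottom_flatten(0.5, 0.3) == 0.5
        assert bottom_flatten(-1.0, 0.3) == pytest.approx(-0.3)

    @given(g=st.floats(0.01, 1.0), eps=st.floats(1e-9, 1e-3))
    def test_continuous_and_monotone_at_zero(self, g, eps):
        gap = abs(bottom_flatten(eps, g) - bottom_flatten(-eps, g))
        assert gap <= (1 + g) * eps * (1 + 1e-12)
        assert bottom_flatten(-eps, g) < bottom_flatten(0.0, g) < bottom_flatten(eps, g)


class TestSynthesizeTarget:
    def test_two_peaks_cosine_geometry(self):
        fs = 32.0
        peaks = np.array([1.0, 2.0])
        raw_min = bottom_flatten(np.cos(np.pi), 0.3)  # -G before renorm
        assert raw_min == pytest.approx(-0.3)
        target = pc.synthesize_target(peaks, 128, fs, G=0.3)
        assert target[32] == pytest.approx(1.0)
        assert target[64] == pytest.approx(1.0)
        assert target.min() == pytest.approx(-1.0)  # renormalized
        for k in (32, 64):
            assert np.argmax(target[k - 4 : k + 5]) == 4

    def test_requires_two_peaks(self):
        with pytest.raises(ValueError):
            pc.synthesize_target(np.array([1.0]), 64, 32.0)


class TestBuildReference:
    def test_recovers_generator_truth(self, clean_record):
        rec, ann = clean_record
        result = pc.build_reference(rec, ann)
        assert not result.rejected
        assert np.max(np.abs(result.record.target - rec.target)) < 0.02

    def test_rejection_via_strict_deviation_bound(self):
        # T_A = T_B = T_M = 0.8, t_A = 5.0, t_B = 13.32 -> n = 10.4,
        # deviation 0.4 from n_round = 10 fails a 0.3 bound
        peaks = np.array([3.4, 4.2, 5.0, 12.52, 13.32])
        zeros = np.zeros(448)
        rec = pc.SignalRecord(
            ppg=zeros, acc_x=zeros, acc_y=zeros, acc_z=zeros, sampling_rate=32.0
        )
        ann = pc.PeakAnnotation(peaks, 5.5, 12.4)
        result = pc.build_reference(rec, ann, max_dev=0.3)
        assert result.rejected
        assert result.record.target is None
        assert result.gap.n == pytest.approx(10.4)
        # the paper's literal bound (0.5) accepts the same annotation
        assert not pc.build_reference(rec, ann).rejected

    def test_no_gap_beats_needed(self):
        # windows nearly abut (t_B - t_A ~ one period): n_round == 1,
        # zero inserted peaks
        peaks = np.array([1.0, 2.0, 3.0, 4.0, 4.6, 5.0])
        zeros = np.zeros(192)
        rec = pc.SignalRecord(
            ppg=zeros, acc_x=zeros, acc_y=zeros, acc_z=zeros, sampling_rate=32.0
        )
        ann = pc.PeakAnnotation(peaks, 4.2, 4.5)
        result = pc.build_reference(rec, ann)
        assert result.gap.n_round == 1
        assert len(result.gap.inserted_peaks) == 0
        assert not result.rejected
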