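import numpy as np
import pytest

from calseize.events import detect_events
from calseize.seizures import (
    align_seizures,
    detect_seizures,
    normalize_to_control,
    seizing_fraction,
    seizure_metrics,
)
from conftest import make_dff


class TestDetectSeizures:
    def test_peak_below_100_is_not_a_seizure(self):
        dff = np.zeros(60)
        dff[20:30] = 80.0
        assert detect_seizures(make_dff(dff, fs=1.0)) == []

    def test_triangle_crossings_match_analytic_geometry(self, triangle_trace):
        # 0 -> 150% over 30 s, back over 30 s: 50% crossings at 10 s and 50 s
        szs = detect_seizures(triangle_trace)
        assert len(szs) == 1
        sz = szs[0]
        dt = 1.0
        assert sz.amplitude_pct == pytest.approx(150.0)
        assert abs(sz.onset_s - 10.0) <= dt
        assert abs(sz.offset_s - 50.0) <= dt
        assert abs(sz.duration_s - 40.0) <= 2 * dt
        assert sz.peak_time_s == pytest.approx(30.0)

    def test_plateau_exactly_at_100_counts(self):
        dff = np.zeros(40)
        dff[10:20] = 100.0  # "at least 100%" is inclusive
        szs = detect_seizures(make_dff(dff, fs=1.0))
        assert len(szs) == 1

    def test_trace_ending_above_boundary_is_truncated(self):
        dff = np.zeros(40)
        dff[30:] = 120.0
        szs = detect_seizures(make_dff(dff, fs=1.0))
        assert len(szs) == 1 and szs[0].truncated
        assert szs[0].offset_s == pytest.approx(40.0)

    def test_agrees_with_event_detector_at_boundary_threshold(self, rng):
        # every seizure is a >=50% event whose amplitude reaches 100%
        for _ in range(50):
            dff = np.abs(rng.normal(0, 60.0, 150))
            tr = make_dff(dff, fs=1.0)
            szs = detect_seizures(tr)
            evs = [e for e in detect_events(tr, 50.0) if e.amplitude_pct >= 100.0]
            assert len(szs) == len(evs)
            for s, e in zip(szs, evs):
                assert s.onset_s == e.onset_s
                assert s.amplitude_pct == e.amplitude_pct


class TestAlignment:
    def test_single_seizure_mean_is_its_own_segment(self, triangle_trace):
        szs = detect_seizures(triangle_trace)
        aligned = align_seizures(szs, triangle_trace, pre_s=0.0, post_s=50.0)
        assert aligned.traces.shape[0] == 1
        np.testing.assert_array_equal(aligned.mean_trace, aligned.traces[0])
        valid = ~np.isnan(aligned.traces[0])
        np.testing.assert_array_equal(aligned.sem_trace[valid], 0.0)

    def test_identical_copies_average_to_waveform_with_zero_sem(self, triangle_trace):
        szs = detect_seizures(triangle_trace)
        pairs = [(szs[0], triangle_trace), (szs[0], triangle_trace)]
        aligned = align_seizures(pairs, pre_s=5.0, post_s=40.0)
        valid = ~np.isnan(aligned.mean_trace)
        np.testing.assert_allclose(aligned.sem_trace[valid], 0.0)
        np.testing.assert_allclose(aligned.traces[0], aligned.traces[1], equal_nan=True)

    def test_time_to_peak_of_symmetric_triangle_is_half_the_rise(
        self, triangle_trace
    ):
        # 50% of the 150% maximum is 75% dF/F0, reached at t=15 s on the
        # linear rise; apex at t=30 s -> time to peak = half the rise = 15 s
        szs = detect_seizures(triangle_trace)
        aligned = align_seizures(szs, triangle_trace, pre_s=0.0, post_s=60.0)
        (m,) = seizure_metrics(aligned)
        assert abs(m.time_to_peak_s - 15.0) <= 1.0

    def test_sem_shrinks_like_inverse_sqrt_n(self, rng):
        # i.i.d. noisy copies of one waveform: SEM ~ sigma/sqrt(n)
        base = np.zeros(200)
        base[50:90] = 150.0
        sigma = 10.0

        def mean_sem(n):
            traces = [make_dff(base + rng.normal(0, sigma, base.size), fs=1.0)
                      for _ in range(n)]
            pairs = []
            for tr in traces:
                szs = detect_seizures(tr)
                pairs.append((szs[0], tr))
            aligned = align_seizures(pairs, pre_s=0.0, post_s=30.0)
            return float(np.nanmean(aligned.sem_trace))

        s4, s16 = mean_sem(4), mean_sem(16)
        assert s16 < s4
        assert s4 / s16 == pytest.approx(2.0, rel=0.35)

    def test_empty_seizure_list_rejected(self, triangle_trace):
        with pytest.raises(ValueError):
            align_seizures([], triangle_trace)


class TestSeizureMetrics:
    def test_rectangle_auc_and_zero_time_to_peak(self):
        dff = np.zeros(40)
        dff[10:20] = 120.0  # 120% for 10 s
        tr = make_dff(dff, fs=1.0)
        szs = detect_seizures(tr)
        aligned = align_seizures(szs, tr, pre_s=0.0, post_s=15.0)
        (m,) = seizure_metrics(aligned)
        # first aligned frame is already maximal
        assert m.time_to_peak_s == 0.0
        # trapezoid of the sampled rectangle: 9 full intervals + 2 half ramps
        t = aligned.time_axis_s
        expected = np.trapezoid(np.nan_to_num(aligned.traces[0]), t)
        assert m.auc == pytest.approx(expected)
        assert m.auc == pytest.approx(1200.0, rel=0.1)

    def test_scaling_doubles_auc_but_not_time_to_peak(self, triangle_trace):
        szs = detect_seizures(triangle_trace)
        a1 = align_seizures(szs, triangle_trace, pre_s=0.0, post_s=50.0)
        doubled = make_dff(triangle_trace.dff_pct * 2.0, fs=1.0)
        szs2 = detect_seizures(doubled)
        a2 = align_seizures(szs2, doubled, pre_s=0.0, post_s=50.0)
        (m1,), (m2,) = seizure_metrics(a1), seizure_metrics(a2)
        assert m2.auc == pytest.approx(2.0 * m1.auc, rel=0.05)
        assert m2.time_to_peak_s == pytest.approx(m1.time_to_peak_s, abs=1.0)

    def test_normalize_to_control(self):
        out = normalize_to_control([2.0, 4.0], [1.0, 3.0])
        np.testing.assert_allclose(out, [1.0, 2.0])
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [0.0])


class TestSeizingFraction:
    @pytest.mark.parametrize(
        "n,total,decimals,expected",
        [
            (12, 21, 2, 57.14),
            (21, 35, 2, 60.00),
            (20, 39, 1, 51.3),
            (6, 38, 1, 15.8),
            (0, 10, 2, 0.0),
            (38, 38, 2, 100.0),
        ],
    )
    def test_reported_fractions(self, n, total, decimals, expected):
        assert seizing_fraction(n, total, decimals) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            seizing_fraction(1, 0)
        with pytest.raises(ValueError):
            seizing_fraction(5, 3)
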