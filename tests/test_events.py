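import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from calseize.events import (
    CaEvent,
    classify_tiers,
    compute_auc,
    detect_events,
    exclude_seizure_like,
    summarize_larva,
)
from conftest import make_dff


class TestDetectEvents:
    def test_flat_trace_yields_no_events(self):
        assert detect_events(make_dff(np.zeros(100)), 5.0) == []

    def test_boxcar_pulse_boundaries_amplitude_duration(self):
        fs = 1.0
        dff = np.zeros(40)
        dff[10:16] = 8.0  # 8% from t=10 s to t=16 s
        evs = detect_events(make_dff(dff, fs=fs), 5.0)
        assert len(evs) == 1
        ev = evs[0]
        assert ev.amplitude_pct == 8.0
        assert ev.onset_s == 10.0
        assert ev.offset_s == 16.0
        assert abs(ev.duration_s - 6.0) <= 1.0 / fs
        assert not ev.truncated

    def test_subthreshold_gap_never_merges_events(self):
        dff = np.zeros(50)
        dff[5:10] = 8.0
        dff[20:25] = 8.0
        evs = detect_events(make_dff(dff, fs=1.0), 5.0)
        assert len(evs) == 2
        assert evs[0].offset_s <= evs[1].onset_s

    def test_threshold_is_strict_inequality(self):
        dff = np.full(20, 5.0)  # exactly at threshold: "above 5%" excludes it
        assert detect_events(make_dff(dff, fs=1.0), 5.0) == []

    def test_edge_events_flagged_truncated(self):
        dff = np.zeros(30)
        dff[0:4] = 9.0
        dff[27:30] = 9.0
        evs = detect_events(make_dff(dff, fs=1.0), 5.0)
        assert [e.truncated for e in evs] == [True, True]


class TestClassifyTiers:
    def test_pulse_peaking_above_both_tiers_is_in_both(self):
        dff = np.zeros(30)
        dff[10:15] = [6.0, 9.0, 12.0, 9.0, 6.0]
        tiers = classify_tiers(make_dff(dff, fs=1.0), [5.0, 10.0])
        assert len(tiers[5.0]) == 1 and len(tiers[10.0]) == 1

    def test_pulse_peaking_between_tiers_only_in_lower(self):
        dff = np.zeros(30)
        dff[10:13] = 7.0
        tiers = classify_tiers(make_dff(dff, fs=1.0), [5.0, 10.0])
        assert len(tiers[5.0]) == 1 and len(tiers[10.0]) == 0

    def test_band_mode_excludes_events_reaching_next_tier(self):
        dff = np.zeros(30)
        dff[5:8] = 7.0
        dff[15:18] = 12.0
        tiers = classify_tiers(make_dff(dff, fs=1.0), [5.0, 10.0], mode="band")
        assert len(tiers[5.0]) == 1  # the 7% event only
        assert len(tiers[10.0]) == 1

    def test_counts_nested_across_tiers_on_random_traces(self, rng):
        for _ in range(200):
            dff = rng.normal(0.0, 6.0, size=rng.integers(30, 200))
            tr = make_dff(dff, fs=1.0)
            tiers = classify_tiers(tr, [5.0, 10.0])
            assert len(tiers[10.0]) <= len(tiers[5.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        hnp.arrays(
            float,
            st.integers(min_value=10, max_value=120),
            elements=st.floats(-30.0, 60.0, allow_nan=False, allow_infinity=False),
        )
    )
    def test_tier_membership_partitions_detected_events(self, dff):
        # cumulative counts are nested, and band counts sum to the base count
        tr = make_dff(dff, fs=1.0)
        cum = classify_tiers(tr, [5.0, 10.0])
        band = classify_tiers(tr, [5.0, 10.0], mode="band")
        assert len(cum[10.0]) <= len(cum[5.0])
        boundary = sum(1 for e in cum[5.0] if e.amplitude_pct == 10.0)
        assert len(band[5.0]) + len(cum[10.0]) + boundary == len(cum[5.0])


class TestExcludeSeizureLike:
    @pytest.mark.parametrize(
        "amp,dur,kept_and,kept_or",
        [
            (120.0, 60.0, False, False),  # big and long: always removed
            (120.0, 5.0, True, False),    # big but short: AND keeps it
            (40.0, 60.0, True, False),    # small but long: AND keeps it
            (40.0, 5.0, True, True),
        ],
    )
    def test_conjunction_vs_disjunction(self, amp, dur, kept_and, kept_or):
        ev = CaEvent("L", 0.0, dur, 1.0, amp, dur, 5.0)
        assert bool(exclude_seizure_like([ev])) is kept_and
        assert bool(exclude_seizure_like([ev], mode="or")) is kept_or

    def test_never_removes_small_amplitude_events(self, rng):
        evs = [
            CaEvent("L", 0.0, d, 0.0, a, d, 5.0)
            for a, d in zip(rng.uniform(0, 50, 50), rng.uniform(0, 100, 50))
        ]
        assert exclude_seizure_like(evs) == evs


class TestComputeAuc:
    def test_constant_rectangle(self):
        # 10% for 61 samples at 1 Hz spans 60 s -> 600 %*s
        tr = make_dff(np.full(61, 10.0), fs=1.0)
        assert compute_auc(tr) == pytest.approx(600.0)

    def test_zero_trace(self):
        assert compute_auc(make_dff(np.zeros(50), fs=1.0)) == 0.0

    def test_linearity_and_time_reversal(self, rng):
        dff = rng.normal(0, 5, 200)
        tr = make_dff(dff, fs=1.33)
        assert compute_auc(make_dff(3.5 * dff, fs=1.33)) == pytest.approx(
            3.5 * compute_auc(tr)
        )
        assert compute_auc(make_dff(dff[::-1], fs=1.33)) == pytest.approx(compute_auc(tr))

    def test_windows_mode_averages_disjoint_windows(self):
        dff = np.concatenate([np.full(100, 10.0), np.full(100, 30.0)])
        tr = make_dff(dff, fs=1.0)
        got = compute_auc(tr, mode="windows", windows=[(0.0, 100.0), (100.0, 200.0)])
        lo = compute_auc(tr, mode="windows", windows=[(0.0, 100.0)])
        hi = compute_auc(tr, mode="windows", windows=[(100.0, 200.0)])
        assert got == pytest.approx((lo + hi) / 2.0)
        assert lo < hi

    def test_windows_mode_validates_inputs(self):
        tr = make_dff(np.zeros(50), fs=1.0)
        with pytest.raises(ValueError):
            compute_auc(tr, mode="windows", windows=[])
        with pytest.raises(ValueError):
            compute_auc(tr, mode="windows", windows=[(0.0, 500.0)])


class TestSummarizeLarva:
    def _evs(self, amps):
        return [CaEvent("L", i, i + 1, i, a, 1.0, 5.0) for i, a in enumerate(amps)]

    def test_mean_amplitude_and_normalised_auc(self):
        s = summarize_larva({5.0: self._evs([6.0, 10.0])}, auc=200.0,
                            control_aucs=[100.0, 300.0], larva_id="L", group="g")
        assert s.tiers[5.0].mean_amplitude_pct == pytest.approx(8.0)
        assert s.auc_normalized == pytest.approx(1.0)

    def test_zero_events_reported_as_missing(self):
        s = summarize_larva({5.0: []}, 10.0, [10.0], "L", "g")
        assert s.tiers[5.0].event_count == 0
        assert np.isnan(s.tiers[5.0].mean_amplitude_pct)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            summarize_larva({5.0: []}, 10.0, [1.0, -1.0], "L", "g")
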