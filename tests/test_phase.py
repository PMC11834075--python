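"""Slow-oscillation phase, delta waves, bout-edge rates, long/short ratio."""

import numpy as np
import pandas as pd
import pytest

from laminar_swr.core import NREM, REM, Hypnogram
from laminar_swr.phase import (DeltaWaveParams, bout_edge_ripple_rate,
                               compute_so_phase, detect_delta_waves,
                               event_phase_stats, long_short_ratio)

FS = 600.0


def _hyp(n_epochs, state=NREM):
    return Hypnogram(labels=[state] * n_epochs)


class TestSoPhase:
    @pytest.fixture(scope="class")
    def tone_phase(self):
        t = np.arange(int(120 * FS)) / FS
        x = 100.0 * np.cos(2 * np.pi * 1.0 * t)
        phase, covered = compute_so_phase(x, _hyp(12), FS)
        return t, x, phase, covered

    def test_cosine_convention_at_peaks_and_troughs(self, tone_phase):
        t, x, phase, _ = tone_phase
        peaks = (np.arange(10, 110)).astype(int)          # t = k s
        troughs = (np.arange(10, 110) + 0.5)
        for tp in peaks:
            d = phase[int(tp * FS)]
            assert min(d, 360 - d) < 2.0
        for tt in troughs:
            assert abs(phase[int(tt * FS)] - 180.0) < 2.0

    def test_ascending_zero_crossing_at_270(self, tone_phase):
        _, _, phase, _ = tone_phase
        for k in range(10, 100):
            assert abs(phase[int((k + 0.75) * FS)] - 270.0) < 5.0

    def test_phase_advances_monotonically(self, tone_phase):
        _, _, phase, _ = tone_phase
        seg = phase[int(10 * FS):int(100 * FS)]
        unwrapped = np.unwrap(np.radians(seg))
        assert (np.diff(unwrapped) > -1e-6).all()
        advance = np.degrees(unwrapped[-1] - unwrapped[0])
        assert advance == pytest.approx(90 * 360.0, rel=0.01)

    def test_rem_samples_uncovered(self):
        t = np.arange(int(60 * FS)) / FS
        hyp = Hypnogram(labels=[NREM] * 3 + [REM] * 3)
        phase, covered = compute_so_phase(np.cos(2 * np.pi * t), hyp, FS)
        assert covered[:int(30 * FS)].all()
        assert not covered[int(30 * FS):].any()
        assert np.isnan(phase[int(30 * FS):]).all()

    def test_no_nrem_rejected(self):
        with pytest.raises(ValueError):
            compute_so_phase(np.zeros(6000), _hyp(1, REM), FS)


class TestEventPhaseStats:
    def _events(self, peaks):
        return pd.DataFrame({"event_id": np.arange(len(peaks)),
                             "type": "SWR", "peak_s": peaks})

    def test_events_at_troughs(self):
        phase = np.full(int(60 * FS), np.nan)
        t = np.arange(len(phase)) / FS
        phase[:] = (360.0 * t) % 360.0  # 1 Hz rotation
        peaks = np.arange(5, 50) + 0.5  # phase 180
        _, summary = event_phase_stats(self._events(peaks), phase, FS)
        row = summary.iloc[0]
        assert row["circ_mean_deg"] == pytest.approx(180.0, abs=2.0)
        assert row["resultant_length"] > 0.99

    def test_uniform_phases_have_small_resultant(self):
        phase = np.linspace(0.0, 360.0 * 100, int(100 * FS)) % 360.0
        peaks = np.linspace(1.0, 99.0, 36)
        _, summary = event_phase_stats(self._events(peaks), phase, FS)
        assert summary.iloc[0]["resultant_length"] < 0.2

    def test_uncovered_events_excluded_with_count(self):
        phase = np.full(int(10 * FS), np.nan)
        phase[:int(5 * FS)] = 90.0
        table, summary = event_phase_stats(self._events([2.0, 8.0]), phase, FS)
        assert len(table) == 1
        assert summary.attrs["n_excluded"] == 1


class TestDeltaWaves:
    def test_zero_trace_gives_none(self):
        table, counts = detect_delta_waves(np.zeros(int(60 * FS)), FS)
        assert table.empty

    def _biphasic(self, dur_s, amp=50.0, n_s=120.0, t0=60.0):
        rng = np.random.default_rng(8)
        x = rng.normal(scale=1.0, size=int(n_s * FS))
        t = np.arange(int(dur_s * FS)) / (dur_s * FS)
        wave = amp * np.sin(2 * np.pi * t)  # positive peak then trough
        i0 = int(t0 * FS)
        x[i0:i0 + len(t)] += wave
        return x

    def test_injected_300ms_wave_detected_once(self):
        x = self._biphasic(0.300)
        table, counts = detect_delta_waves(x, FS)
        assert len(table) == 1
        row = table.iloc[0]
        assert 60.0 - 0.05 <= row["peak_s"] <= 60.35
        assert row["peak_s"] < row["trough_s"]
        assert counts.iloc[0] == 1

    def test_700ms_wave_rejected_by_duration_bound(self):
        x = self._biphasic(0.700)
        table, _ = detect_delta_waves(x, FS)
        assert table.empty

    def test_count_nonincreasing_in_thresholds(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=int(300 * FS))
        counts = []
        for k in (1.0, 2.0, 3.0):
            p = DeltaWaveParams(peak_sd=k, trough_sd=k)
            table, _ = detect_delta_waves(x, FS, p)
            counts.append(len(table))
        assert counts == sorted(counts, reverse=True)

    def test_degenerate_thresholds_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            detect_delta_waves(rng.normal(size=6000), FS,
                               DeltaWaveParams(peak_threshold_uv=-1.0))


class TestBoutEdgeRates:
    def _events(self, peaks):
        return pd.DataFrame({"event_id": np.arange(len(peaks)),
                             "type": "SWR", "peak_s": peaks,
                             "start_s": peaks, "end_s": peaks})

    def test_short_bout_excluded(self):
        hyp = _hyp(60)  # one 10-min bout
        out = bout_edge_ripple_rate(self._events([10.0]), hyp)
        assert out.empty

    def test_edge_rate_arithmetic(self):
        hyp = _hyp(100)  # 1000 s single bout
        peaks = np.linspace(1.0, 99.0, 10)  # 10 peaks in the first 100 s
        out = bout_edge_ripple_rate(self._events(peaks), hyp,
                                    min_bout_min=15.0, edge_frac=0.10)
        assert len(out) == 1
        assert out.iloc[0]["start_rate_hz"] == pytest.approx(0.1)
        assert out.iloc[0]["end_rate_hz"] == 0.0

    def test_homogeneous_poisson_rates_balance(self):
        rng = np.random.default_rng(11)
        lam = 0.5
        labels = ([NREM] * 120 + [REM] * 6) * 8  # eight 20-min bouts
        hyp = Hypnogram(labels=labels)
        peaks = []
        for _, s0, s1 in hyp.bouts(NREM):
            n = rng.poisson(lam * (s1 - s0))
            peaks.extend(rng.uniform(s0, s1, n))
        out = bout_edge_ripple_rate(self._events(sorted(peaks)), hyp)
        assert len(out) == 8
        assert out["start_rate_hz"].mean() == pytest.approx(lam, rel=0.2)
        assert out["end_rate_hz"].mean() == pytest.approx(lam, rel=0.2)


class TestLongShortRatio:
    def _events(self, durs_ms, types=None):
        durs = np.asarray(durs_ms) / 1000.0
        return pd.DataFrame({
            "type": types if types is not None else ["SWR"] * len(durs),
            "start_s": np.zeros(len(durs)), "end_s": durs,
            "peak_s": durs / 2})

    def test_thirty_long_sixty_short(self):
        ev = self._events([150.0] * 30 + [50.0] * 60)
        ratio, n_long, n_short = long_short_ratio(ev)
        assert ratio == pytest.approx(0.5)
        assert (n_long, n_short) == (30, 60)

    def test_equal_counts_give_one(self):
        ev = self._events([150.0, 50.0] * 5)
        assert long_short_ratio(ev)[0] == pytest.approx(1.0)

    def test_all_long_flagged_undefined(self):
        ev = self._events([150.0] * 5)
        assert np.isnan(long_short_ratio(ev)[0])

    def test_standalone_sws_not_counted(self):
        ev = self._events([150.0, 150.0, 50.0, 500.0],
                          types=["SWR", "R", "cSWR", "SW"])
        ratio, n_long, n_short = long_short_ratio(ev)
        assert (n_long, n_short) == (2, 1)


class TestPhaseRecoveryOnFixture:
    def test_injected_phase_preferences_recovered(self, sim_30min):
        cfg, rec, gt = sim_30min
        labels = []
        for state, s0, s1 in gt.state_schedule:
            labels.extend([state] * int(round((s1 - s0) / 10.0)))
        hyp = Hypnogram(labels=labels)
        phase, _ = compute_so_phase(rec.trace("PFC_shallow"), hyp, rec.fs_hz)
        ev = gt.events_frame().reset_index(names="event_id")
        _, summary = event_phase_stats(ev, phase, rec.fs_hz)
        for _, row in summary.iterrows():
            target = cfg.event_phase_deg[row["type"]]
            d = abs(row["circ_mean_deg"] - target) % 360.0
            assert min(d, 360.0 - d) <= 20.0, row
            assert row["resultant_length"] > 0.8
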