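"""Event detection and R/SW/SWR/cSWR classification."""

import itertools

import numpy as np
import pytest

from laminar_swr.core import Interval
from laminar_swr.detect import (DetectionParams, classify_events,
                                detect_ripples, detect_sharp_waves,
                                envelope, estimate_threshold)
from laminar_swr.preprocess import bandpass
from laminar_swr.synth import generate_noise
from laminar_swr.validate import detection_scores

FS = 600.0


class TestThreshold:
    def test_gaussian_magnitude_gives_mean_plus_5sd(self):
        m = np.random.default_rng(0).normal(size=1_000_000)
        detect, boundary = estimate_threshold(m, 5.0, 0.5)
        assert detect == pytest.approx(5.0, abs=0.05)
        assert boundary == pytest.approx(detect / 2.0)

    def test_constant_magnitude_rejected(self):
        with pytest.raises(ValueError):
            estimate_threshold(np.full(1000, 3.0))

    def test_zero_sd_multiplier_returns_mean(self):
        m = np.random.default_rng(1).normal(loc=2.0, size=100_000)
        detect, _ = estimate_threshold(m, 0.0)
        assert detect == pytest.approx(2.0, abs=0.02)


def _burst(t_center, fwhm, amp, freq, n, fs=FS):
    t = np.arange(n) / fs
    sigma = fwhm / 2.355
    return amp * np.exp(-0.5 * ((t - t_center) / sigma) ** 2) * \
        np.cos(2 * np.pi * freq * (t - t_center))


class TestRipples:
    def test_zero_trace_yields_no_events(self):
        assert detect_ripples(np.zeros(6000), FS) == []

    def test_single_burst_edges_match_bruteforce_oracle(self):
        n = int(120 * FS)
        noise = bandpass(generate_noise(n, FS, 1.0, 1.0, seed=3), FS, 90, 200)
        x = noise + _burst(60.0, 0.12, 10 * np.std(noise) * 5, 150.0, n)
        events = detect_ripples(x, FS)
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.peak_s - 60.0) < 0.02
        # brute-force oracle: scan envelope for half-threshold crossings
        mag = envelope(x, FS)
        detect, boundary = estimate_threshold(mag, 5.0, 0.5)
        core = np.flatnonzero(mag >= detect)
        lo = core[0]
        while lo > 0 and mag[lo - 1] >= boundary:
            lo -= 1
        hi = core[-1]
        while hi < n - 1 and mag[hi + 1] >= boundary:
            hi += 1
        assert abs(ev.start_s - lo / FS) <= 0.010
        assert abs(ev.end_s - hi / FS) <= 0.010

    @pytest.mark.parametrize("gap_ms,n_expected", [(60, 1), (120, 2)])
    def test_merge_rule_at_80ms(self, gap_ms, n_expected):
        # rectangular-envelope bursts give sharp edge-to-edge gaps
        n = int(60 * FS)
        noise = bandpass(generate_noise(n, FS, 1.0, 0.5, seed=4), FS, 90, 200)
        amp = 10 * np.std(noise) * 5
        gap = gap_ms / 1000.0
        t = np.arange(n) / FS
        x = noise.copy()
        for t0 in (30.0, 30.0 + 0.06 + gap):
            sel = (t >= t0) & (t < t0 + 0.06)
            x[sel] += amp * np.cos(2 * np.pi * 150.0 * (t[sel] - t0))
        events = detect_ripples(x, FS)
        assert len(events) == n_expected

    def test_raising_threshold_never_increases_count(self):
        n = int(120 * FS)
        x = bandpass(generate_noise(n, FS, 1.0, 1.0, seed=5), FS, 90, 200)
        for t in (55.0, 56.5, 58.0):
            x += _burst(t, 0.08, np.std(x) * 30, 150.0, n)
        counts = [len(detect_ripples(x, FS, DetectionParams(threshold_sd=sd)))
                  for sd in (2.0, 4.0, 6.0, 10.0)]
        assert counts == sorted(counts, reverse=True)


class TestSharpWaves:
    def test_zero_trace_yields_none(self):
        assert detect_sharp_waves(np.zeros(6000), FS) == []

    def test_injected_trough_found_at_minimum(self):
        # the detector contract expects a 2-20 Hz band-passed trace
        x = bandpass(generate_noise(int(60 * FS), FS, 1.0, 1.0, seed=6),
                     FS, 2, 20)
        t = np.arange(int(0.06 * FS)) / (0.06 * FS)
        trough = -8.0 * np.sin(np.pi * t)
        i0 = int(30 * FS)
        x[i0:i0 + len(t)] += trough * np.std(x)
        events = detect_sharp_waves(x, FS)
        assert len(events) == 1
        assert abs(events[0].peak_s - (i0 + len(t) / 2) / FS) < 0.02
        assert x[int(round(events[0].peak_s * FS))] == x[
            int(events[0].start_s * FS):int(events[0].end_s * FS) + 1].min()

    def test_positive_deflection_ignored(self):
        x = bandpass(generate_noise(int(60 * FS), FS, 1.0, 1.0, seed=7),
                     FS, 2, 20)
        x[int(30 * FS):int(30.06 * FS)] += 8.0 * np.std(x)
        assert detect_sharp_waves(x, FS) == []


def _oracle_classify(ripples, sws, mode="literal"):
    """Independent brute-force endpoint-containment classifier."""
    out = []
    used = set()
    for r in ripples:
        k = 0
        for j, s in enumerate(sws):
            if mode == "literal":
                hit = (r[0] <= s[2] <= r[2]) or (r[0] <= s[0] <= r[2])
            else:
                hit = max(r[0], s[0]) <= min(r[2], s[2])
            if hit:
                k += 1
                used.add(j)
        out.append("R" if k == 0 else ("SWR" if k == 1 else "cSWR"))
    n_standalone_sw = sum(1 for j in range(len(sws)) if j not in used)
    return out, n_standalone_sw


class TestClassification:
    def test_lone_ripple_is_R(self):
        df = classify_events([Interval(0.0, 0.05, 0.1)], [])
        assert list(df["type"]) == ["R"]

    def test_ripple_with_two_sws_is_cswr(self):
        df = classify_events(
            [Interval(0.0, 0.05, 0.1)],
            [Interval(0.01, 0.02, 0.04), Interval(0.05, 0.06, 0.09)])
        assert list(df["type"]) == ["cSWR"]
        assert df.iloc[0]["n_sw_overlaps"] == 2

    def test_sw_strictly_containing_ripple_literal_vs_intersection(self):
        ripple = [Interval(1.0, 1.05, 1.1)]
        sw = [Interval(0.9, 1.0, 1.2)]  # contains the ripple entirely
        literal = classify_events(ripple, sw, mode="literal")
        assert sorted(literal["type"]) == ["R", "SW"]
        inter = classify_events(ripple, sw, mode="intersection")
        assert list(inter["type"]) == ["SWR"]

    def test_exhaustive_lattice_matches_oracle(self):
        # every ripple/SW endpoint configuration on a 12-point lattice
        pts = range(12)
        for rs, re in itertools.combinations(pts, 2):
            for ss, se in itertools.combinations(pts, 2):
                ripples = [(float(rs), (rs + re) / 2.0, float(re))]
                sws = [(float(ss), (ss + se) / 2.0, float(se))]
                for mode in ("literal", "intersection"):
                    df = classify_events(ripples, sws, mode=mode)
                    types, n_sw = _oracle_classify(ripples, sws, mode)
                    got_r = df[df["type"] != "SW"]
                    assert list(got_r["type"]) == types, (ripples, sws, mode)
                    assert (df["type"] == "SW").sum() == n_sw

    def test_duplicate_intervals_deduplicated_with_warning(self):
        with pytest.warns(UserWarning):
            df = classify_events(
                [Interval(0.0, 0.05, 0.1), Interval(0.0, 0.05, 0.1)], [])
        assert len(df) == 1

    def test_every_detection_appears_exactly_once(self, detected_30min):
        ev = detected_30min["events"]
        # ripples -> one of R/SWR/cSWR; SWs -> standalone SW or member
        assert set(ev["type"]) <= {"R", "SW", "SWR", "cSWR"}
        assert ev["event_id"].is_unique
        assert (ev[ev["type"] == "R"]["n_sw_overlaps"] == 0).all()
        assert (ev[ev["type"] == "SWR"]["n_sw_overlaps"] == 1).all()
        assert (ev[ev["type"] == "cSWR"]["n_sw_overlaps"] >= 2).all()


def test_recall_and_precision_on_default_fixture(detected_30min):
    scores = detection_scores(detected_30min["gt"],
                              detected_30min["nrem_events"])
    assert (scores["recall"] >= 0.85).all(), scores
    assert (scores["precision"] >= 0.85).all(), scores
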