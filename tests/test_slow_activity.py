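"""Delta power and discrete slow-wave detection against analytic oracles."""

import numpy as np
import pytest

from sleepasym.eeg_io import StageSegments
from sleepasym.slow_activity import (
    SlowWaveEvent,
    bandpass,
    compute_delta_power,
    detect_slow_waves,
    negative_half_waves,
    summarize_slow_waves,
)

from conftest import FS, inject_half_sine, make_recording, segments


LEFT_ONLY = {"left": ("F3-C3",)}


def _background(n):
    """Weak 5 Hz carrier: its 0.1 s half-waves fail the duration criterion,
    unlike an all-zero trace whose numerical filter residue forms
    arbitrary-duration ghost half-waves."""
    t = np.arange(n) / FS
    return 0.5 * np.sin(2 * np.pi * 5.0 * t)


def _detection_pair(bipolar_trace, avgref_trace=None):
    """Recordings wired so 'F3-C3' is checked against average-referenced F3."""
    if avgref_trace is None:
        avgref_trace = bipolar_trace
    bp = make_recording(["F3-C3"], bipolar_trace[None, :], sides=["left"])
    ar = make_recording(["F3"], avgref_trace[None, :])
    return bp, ar


# ---------------------------------------------------------------- delta power

def test_delta_power_of_pure_tone_is_half_amplitude_squared():
    amp = 40.0
    n = int(120 * FS)
    t = np.arange(n) / FS
    rec = make_recording(["F3-C3"], (amp * np.sin(2 * np.pi * 2.0 * t))[None, :],
                         sides=["left"])
    res = compute_delta_power(rec, segments([(0.0, 120.0)]))
    assert res.channel_power["F3-C3"] == pytest.approx(amp**2 / 2.0, rel=0.05)


def test_delta_power_excludes_out_of_band_tone():
    n = int(120 * FS)
    t = np.arange(n) / FS
    sig = 40.0 * np.sin(2 * np.pi * 10.0 * t)
    rec = make_recording(["F3-C3"], sig[None, :], sides=["left"])
    res = compute_delta_power(rec, segments([(0.0, 120.0)]))
    total = 40.0**2 / 2.0
    assert res.channel_power["F3-C3"] < 0.01 * total


def test_delta_power_of_white_noise_matches_flat_spectrum():
    rng = np.random.default_rng(11)
    sd = 15.0
    n = int(300 * FS)
    rec = make_recording(["F3-C3"], rng.normal(0, sd, n)[None, :], sides=["left"])
    res = compute_delta_power(rec, segments([(0.0, 300.0)]))
    expected = sd**2 * 3.5 / (FS / 2.0)  # flat density sigma^2/f_nyq over 3.5 Hz
    assert res.channel_power["F3-C3"] == pytest.approx(expected, rel=0.1)


def test_delta_power_windows_do_not_straddle_gaps():
    rng = np.random.default_rng(4)
    n = int(100 * FS)
    sig = rng.normal(0, 10.0, n)
    sig[int(40 * FS): int(60 * FS)] = 1e4  # huge artifact between segments
    rec = make_recording(["F3-C3"], sig[None, :], sides=["left"])
    res = compute_delta_power(rec, segments([(0.0, 40.0), (60.0, 100.0)]))
    clean = compute_delta_power(
        make_recording(["F3-C3"], sig[None, :int(40 * FS)], sides=["left"]),
        segments([(0.0, 40.0)]),
    )
    assert res.channel_power["F3-C3"] == pytest.approx(
        clean.channel_power["F3-C3"], rel=0.3
    )


def test_delta_power_hemisphere_mean():
    n = int(60 * FS)
    t = np.arange(n) / FS
    tone = 30.0 * np.sin(2 * np.pi * 1.5 * t)
    sig = np.vstack([tone, 2.0 * tone, np.zeros(n)])
    rec = make_recording(["F3-C3", "F7-T7", "F4-C4"], sig,
                         sides=["left", "left", "right"])
    res = compute_delta_power(rec, segments([(0.0, 60.0)]))
    expected_left = np.mean(
        [res.channel_power["F3-C3"], res.channel_power["F7-T7"]]
    )
    assert res.hemisphere_power["left"] == pytest.approx(expected_left)


# ---------------------------------------------------------------- half-waves

def test_negative_half_waves_on_sine_match_analytic_boundaries():
    f = 1.0
    n = int(5 * FS)
    t = np.arange(n) / FS
    x = np.sin(2 * np.pi * f * t)
    events = negative_half_waves(x, FS)
    assert len(events) == 4  # negative lobes at 0.5-1, 1.5-2, 2.5-3, 3.5-4 s
    s, trough, e = events[0]
    assert s / FS == pytest.approx(0.5, abs=2 / FS)
    assert trough / FS == pytest.approx(0.75, abs=2 / FS)
    assert e / FS == pytest.approx(1.0, abs=2 / FS)


def test_negative_half_waves_brute_force_oracle(rng):
    x = rng.normal(size=2048)
    events = negative_half_waves(x, FS)
    for s, trough, e in events:
        assert np.all(x[s:e] < 0)
        assert x[s - 1] >= 0 and x[e] >= 0
        assert x[trough] == x[s:e].min()


# ---------------------------------------------------------------- detection

def _strong(events, floor_uv=5.0):
    """Drop sub-floor ghosts: the zero-phase band-pass rings around large
    deflections, producing qualifying-duration half-waves below a few uV."""
    return [ev for ev in events if ev.amplitude_uv > floor_uv]


def test_detects_injected_half_sine():
    n = int(60 * FS)
    trace = _background(n)
    inject_half_sine(trace, FS, onset_s=10.0, duration_s=0.5, amplitude_uv=80.0)
    bp, ar = _detection_pair(trace)
    events = _strong(
        detect_slow_waves(bp, ar, segments([(0.0, 60.0)]), channels=LEFT_ONLY)
    )
    assert len(events) == 1
    ev = events[0]
    # the band-pass shortens and attenuates the half-wave; amplitude remains
    # proportional to the injection (scale equivariance is tested separately)
    assert ev.duration_s == pytest.approx(0.5, abs=0.15)
    assert 40.0 < ev.amplitude_uv <= 80.0
    assert ev.trough_time_s == pytest.approx(10.25, abs=0.1)
    assert ev.slope_uv_per_s == pytest.approx(ev.amplitude_uv / ev.time_to_trough_s)


def test_duration_criterion_rejects_too_short_injection():
    n = int(60 * FS)
    trace = _background(n)
    inject_half_sine(trace, FS, onset_s=10.0, duration_s=0.15, amplitude_uv=80.0)
    bp, ar = _detection_pair(trace)
    events = _strong(
        detect_slow_waves(bp, ar, segments([(0.0, 60.0)]), channels=LEFT_ONLY)
    )
    assert events == []


def test_duration_criterion_exact_on_filtered_domain_composite():
    """Half-waves built directly in the filtered domain (no refiltering, so no
    ringing): the duration criterion keeps exactly the in-range ones, with
    zero false inclusions."""
    n = int(60 * FS)
    trace = np.zeros(n)
    durations = [0.1, 0.2, 0.5, 0.9, 1.3]
    for i, dur in enumerate(durations):
        inject_half_sine(trace, FS, onset_s=5.0 + 10.0 * i, duration_s=dur,
                         amplitude_uv=80.0)
    kept = [
        (s / FS, (e - s) / FS)
        for s, t, e in negative_half_waves(trace, FS)
        if 0.25 <= (e - s) / FS <= 1.0
    ]
    assert len(kept) == 2
    assert kept[0][0] == pytest.approx(25.0, abs=0.05)
    assert kept[1][0] == pytest.approx(35.0, abs=0.05)


def test_referential_cross_check_rejects_sign_inverted_reference():
    n = int(60 * FS)
    trace = _background(n)
    inject_half_sine(trace, FS, onset_s=10.0, duration_s=0.5, amplitude_uv=80.0)
    bp, ar = _detection_pair(trace, avgref_trace=-trace)
    events = detect_slow_waves(bp, ar, segments([(0.0, 60.0)]), channels=LEFT_ONLY)
    assert events == []


def test_events_outside_segments_are_dropped():
    n = int(60 * FS)
    trace = _background(n)
    inject_half_sine(trace, FS, onset_s=10.0, duration_s=0.5, amplitude_uv=80.0)
    inject_half_sine(trace, FS, onset_s=40.0, duration_s=0.5, amplitude_uv=80.0)
    bp, ar = _detection_pair(trace)
    events = _strong(
        detect_slow_waves(bp, ar, segments([(0.0, 20.0)]), channels=LEFT_ONLY)
    )
    assert len(events) == 1 and events[0].trough_time_s < 20.0


def test_amplitude_floor_filters_small_waves():
    n = int(60 * FS)
    trace = _background(n)
    inject_half_sine(trace, FS, onset_s=10.0, duration_s=0.5, amplitude_uv=80.0)
    inject_half_sine(trace, FS, onset_s=30.0, duration_s=0.5, amplitude_uv=10.0)
    bp, ar = _detection_pair(trace)
    seg = segments([(0.0, 60.0)])
    no_floor = _strong(detect_slow_waves(bp, ar, seg, channels=LEFT_ONLY))
    floored = detect_slow_waves(
        bp, ar, seg, channels=LEFT_ONLY, min_amplitude_uv=30.0
    )
    assert len(no_floor) == 2
    assert len(floored) == 1 and floored[0].amplitude_uv > 30.0


def test_detection_is_scale_equivariant(rng):
    n = int(30 * FS)
    trace = rng.normal(0, 20.0, n)
    bp, ar = _detection_pair(trace)
    bp3, ar3 = _detection_pair(3.0 * trace)
    seg = segments([(0.0, 30.0)])
    ev1 = detect_slow_waves(bp, ar, seg, channels=LEFT_ONLY)
    ev3 = detect_slow_waves(bp3, ar3, seg, channels=LEFT_ONLY)
    assert len(ev1) == len(ev3)
    for a, b in zip(ev1, ev3):
        assert a.onset_s == b.onset_s and a.offset_s == b.offset_s
        assert b.amplitude_uv == pytest.approx(3.0 * a.amplitude_uv)


# ---------------------------------------------------------------- summaries

def _event(channel, onset, dur, trough_frac, amp):
    return SlowWaveEvent(
        channel=channel,
        onset_s=onset,
        offset_s=onset + dur,
        trough_time_s=onset + trough_frac * dur,
        amplitude_uv=amp,
    )


def test_summarize_density_and_slope():
    seg = segments([(0.0, 1200.0)])  # 20 minutes
    events = [_event("F3-C3", 10.0 * i, 0.5, 0.5, 80.0) for i in range(30)]
    out = summarize_slow_waves(events, seg, channels=LEFT_ONLY)
    assert out["left"]["sw_density"] == pytest.approx(1.5)
    assert out["left"]["sw_amplitude"] == pytest.approx(80.0)
    assert out["left"]["sw_duration"] == pytest.approx(0.5)
    assert out["left"]["sw_slope"] == pytest.approx(80.0 / 0.25)


def test_summarize_no_events_gives_zero_density_nan_morphology():
    out = summarize_slow_waves([], segments([(0.0, 1200.0)]), channels=LEFT_ONLY)
    assert out["left"]["sw_density"] == 0.0
    assert np.isnan(out["left"]["sw_amplitude"])


def test_event_invariants_enforced():
    with pytest.raises(ValueError):
        SlowWaveEvent(channel="F3-C3", onset_s=1.0, offset_s=0.5,
                      trough_time_s=0.8, amplitude_uv=50.0)
    with pytest.raises(ValueError):
        SlowWaveEvent(channel="F3-C3", onset_s=0.0, offset_s=0.5,
                      trough_time_s=0.25, amplitude_uv=-5.0)


def test_bandpass_attenuates_out_of_band():
    n = int(30 * FS)
    t = np.arange(n) / FS
    x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 30.0 * t)
    y = bandpass(x, FS, 0.5, 4.0)
    # the 1 Hz component survives, the 30 Hz component is strongly attenuated
    mid = slice(int(5 * FS), int(25 * FS))
    assert np.std(y[mid]) == pytest.approx(np.std(np.sin(2 * np.pi * t[mid])), rel=0.05)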