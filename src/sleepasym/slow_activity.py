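"""Delta-band power and discrete sleep slow-wave detection.

Slow oscillations in ongoing NREM activity are quantified as Welch spectral
power in the 0.5-4 Hz band on the lateralized bipolar traces.  Discrete slow
waves are negative half-waves of the 0.5-4 Hz Butterworth-filtered bipolar
trace lasting 0.25-1 s between a positive-to-negative and the following
negative-to-positive zero crossing, retained only if a qualifying negative
half-wave of the average-referenced anode trace overlaps the bipolar trough
(slow waves are by definition negative potentials, so the referential check
removes events whose bipolar polarity is an artefact of the derivation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg_io import Recording, StageSegments, SW_CHANNELS

__all__ = [
    "SlowWaveEvent",
    "DeltaPowerResult",
    "bandpass",
    "negative_half_waves",
    "compute_delta_power",
    "detect_slow_waves",
    "summarize_slow_waves",
]

DELTA_BAND = (0.5, 4.0)


@dataclass(frozen=True)
class SlowWaveEvent:
    """One detected slow wave with its morphology features.

    ``amplitude_uv`` is the absolute value of the trough minimum (a),
    ``time_to_trough_s`` the latency from onset zero-crossing to the trough
    (b), and the slope is a/b.
    """

    channel: str
    onset_s: float
    offset_s: float
    trough_time_s: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if not (self.onset_s < self.trough_time_s < self.offset_s):
            raise ValueError("trough must lie strictly inside the event")
        if self.amplitude_uv <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def time_to_trough_s(self) -> float:
        return self.trough_time_s - self.onset_s

    @property
    def slope_uv_per_s(self) -> float:
        return self.amplitude_uv / self.time_to_trough_s


@dataclass
class DeltaPowerResult:
    """Per-channel delta band power (uV^2) and hemispheric aggregates."""

    channel_power: dict[str, float]
    hemisphere_power: dict[str, float]  # mean over that side's channels
    segment_minutes: float


def bandpass(
    x: np.ndarray, sampling_rate: float, low: float, high: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass filter."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def negative_half_waves(
    filtered: np.ndarray, sampling_rate: float
) -> list[tuple[int, int, int]]:
    """All negative half-waves as (onset, trough, offset) sample indices.

    A half-wave runs from a positive-to-negative zero crossing to the next
    negative-to-positive crossing; the trough is the sample of the minimum.
    """
    neg = filtered < 0
    # crossing at i means sign changes between samples i-1 and i
    starts = np.flatnonzero(~neg[:-1] & neg[1:]) + 1
    ends = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1
    events = []
    j = 0
    for s in starts:
        while j < len(ends) and ends[j] <= s:
            j += 1
        if j == len(ends):
            break
        e = ends[j]
        trough = s + int(np.argmin(filtered[s:e]))
        events.append((int(s), trough, int(e)))
    return events


def compute_delta_power(
    traces: Recording,
    segments: StageSegments,
    band: tuple[float, float] = DELTA_BAND,
    window_s: float = 4.0,
) -> DeltaPowerResult:
    """Welch delta-band power per channel over scored segments.

    Hamming windows of ``window_s`` with 50% overlap are laid within each
    segment interval separately, so no window straddles a gap; per-interval
    periodograms are averaged weighted by their number of windows.  Band
    power is the integral of the spectral density over ``band``.
    """
    fs = traces.sampling_rate
    if band[1] > fs / 2:
        raise ValueError("band exceeds the Nyquist frequency")
    nperseg = int(round(window_s * fs))
    slices = [sl for sl in segments.slices(fs) if sl.stop - sl.start >= nperseg]
    if not slices:
        raise ValueError("no segment is at least one Welch window long")

    channel_power: dict[str, float] = {}
    step = nperseg // 2
    for idx, label in enumerate(traces.channel_labels):
        psd_sum = None
        weight = 0
        for sl in slices:
            seg = traces.signal[idx, sl]
            freqs, psd = sps.welch(
                seg, fs=fs, window="hamming", nperseg=nperseg, noverlap=step
            )
            n_windows = 1 + (len(seg) - nperseg) // step
            psd_sum = psd * n_windows if psd_sum is None else psd_sum + psd * n_windows
            weight += n_windows
        psd_mean = psd_sum / weight
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        channel_power[label] = float(np.trapezoid(psd_mean[in_band], freqs[in_band]))

    hemisphere_power: dict[str, float] = {}
    if traces.sides is not None:
        for side in ("left", "right"):
            vals = [
                channel_power[lab]
                for lab, s in zip(traces.channel_labels, traces.sides)
                if s == side
            ]
            if vals:
                hemisphere_power[side] = float(np.mean(vals))
    return DeltaPowerResult(
        channel_power=channel_power,
        hemisphere_power=hemisphere_power,
        segment_minutes=segments.total_minutes,
    )


def _qualifying_half_waves(
    filtered: np.ndarray,
    sampling_rate: float,
    min_dur_s: float,
    max_dur_s: float,
    min_amplitude_uv: float | None,
) -> list[tuple[int, int, int]]:
    out = []
    for s, t, e in negative_half_waves(filtered, sampling_rate):
        dur = (e - s) / sampling_rate
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        if min_amplitude_uv is not None and -filtered[t] < min_amplitude_uv:
            continue
        out.append((s, t, e))
    return out


def detect_slow_waves(
    bipolar: Recording,
    avgref: Recording,
    segments: StageSegments,
    channels: dict[str, tuple[str, ...]] | None = None,
    band: tuple[float, float] = DELTA_BAND,
    min_dur_s: float = 0.25,
    max_dur_s: float = 1.0,
    min_amplitude_uv: float | None = None,
    filter_order: int = 4,
) -> list[SlowWaveEvent]:
    """Detect slow waves on the four lateralized fronto-central/temporal pairs.

    Both derivations are filtered to ``band``; negative half-waves of the
    bipolar trace lasting ``min_dur_s``..``max_dur_s`` are kept when a
    qualifying negative half-wave of the average-referenced anode electrode
    contains the bipolar trough time, and when the event lies entirely inside
    the scored segments.  ``min_amplitude_uv`` is an optional trough floor
    (off by default; the duration criterion is the defining one).
    """
    if bipolar.sampling_rate != avgref.sampling_rate:
        raise ValueError("bipolar and average-referenced recordings must be sample-aligned")
    if bipolar.n_samples != avgref.n_samples:
        raise ValueError("bipolar and average-referenced recordings must be sample-aligned")
    fs = bipolar.sampling_rate
    if channels is None:
        channels = SW_CHANNELS
    in_segment = segments.sample_mask(bipolar.n_samples, fs)

    events: list[SlowWaveEvent] = []
    for side, labels in channels.items():
        for label in labels:
            anode = label.split("-")[0]
            bp = bandpass(bipolar.trace(label), fs, *band, order=filter_order)
            ar = bandpass(avgref.trace(anode), fs, *band, order=filter_order)
            ref_hws = _qualifying_half_waves(ar, fs, min_dur_s, max_dur_s, None)
            ref_starts = np.array([s for s, _, _ in ref_hws], dtype=int)
            ref_ends = np.array([e for _, _, e in ref_hws], dtype=int)
            for s, t, e in _qualifying_half_waves(
                bp, fs, min_dur_s, max_dur_s, min_amplitude_uv
            ):
                if not in_segment[s:e].all():
                    continue
                # referential cross-check: trough inside an average-reference half-wave
                k = np.searchsorted(ref_starts, t, side="right") - 1
                if k < 0 or t >= ref_ends[k]:
                    continue
                events.append(
                    SlowWaveEvent(
                        channel=label,
                        onset_s=s / fs,
                        offset_s=e / fs,
                        trough_time_s=t / fs,
                        amplitude_uv=float(-bp[t]),
                    )
                )
    return events


def summarize_slow_waves(
    events: list[SlowWaveEvent],
    segments: StageSegments,
    channels: dict[str, tuple[str, ...]] | None = None,
    central: str = "median",
) -> dict[str, dict[str, float]]:
    """Per-hemisphere slow-wave density, amplitude, duration and slope.

    Density is events per minute of scored data.  Amplitude, duration and
    slope are summarized per channel by ``central`` (median by default) and
    averaged within the hemisphere; with no events they are NaN (density 0).
    """
    if segments.total_minutes <= 0:
        raise ValueError("segments have zero duration")
    if channels is None:
        channels = SW_CHANNELS
    stat = {"median": np.median, "mean": np.mean}[central]

    out: dict[str, dict[str, float]] = {}
    for side, labels in channels.items():
        per_channel = {
            "sw_density": [],
            "sw_amplitude": [],
            "sw_duration": [],
            "sw_slope": [],
        }
        for label in labels:
            evs = [ev for ev in events if ev.channel == label]
            per_channel["sw_density"].append(len(evs) / segments.total_minutes)
            if evs:
                per_channel["sw_amplitude"].append(stat([ev.amplitude_uv for ev in evs]))
                per_channel["sw_duration"].append(stat([ev.duration_s for ev in evs]))
                per_channel["sw_slope"].append(stat([ev.slope_uv_per_s for ev in evs]))
        out[side] = {
            key: float(np.mean(vals)) if vals else (0.0 if key == "sw_density" else float("nan"))
            for key, vals in per_channel.items()
        }
        if not any(ev.channel in labels for ev in events):
            out[side]["sw_amplitude"] = float("nan")
            out[side]["sw_duration"] = float("nan")
            out[side]["sw_slope"] = float("nan")
    return out
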