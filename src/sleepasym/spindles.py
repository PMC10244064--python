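"""Sleep spindle detection and their phase-locking to slow oscillations.

Spindles are detected during NREM 2 on the centro-inferior-temporal bipolar
channels with an RMS-envelope amplitude detector: the trace is band-passed
11-16 Hz, the root-mean-square envelope (0.2 s moving window) must exceed the
segment's mean + 1.5 SD for 0.5-3 s; nearby events are merged.  Locking to
slow oscillations is quantified with inter-trial coherence (ITC) of the
0.5-4 Hz Hilbert phase sampled at each spindle's maximal trough:

    ITC = (1/N) | sum_k exp(i phi_k) |

ITC is used instead of phase-amplitude coupling precisely because it is
insensitive to spindle amplitude, which is itself an analysed feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert

from .eeg_io import StageSegments
from .slow_activity import DELTA_BAND, bandpass

__all__ = [
    "SpindleEvent",
    "PhaseSet",
    "SpindleParams",
    "detect_spindles",
    "spindle_features",
    "slow_osc_phase_at_troughs",
    "itc",
]

SPINDLE_BAND = (11.0, 16.0)


@dataclass(frozen=True)
class SpindleEvent:
    """One detected spindle; the trough is the minimum of the 11-16 Hz trace."""

    channel: str
    onset_s: float
    offset_s: float
    trough_time_s: float
    amplitude_uv: float = float("nan")  # filled by spindle_features
    truncated_epoch: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.trough_time_s <= self.offset_s):
            raise ValueError("trough must lie within the event")
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class PhaseSet:
    """Slow-oscillation phases (radians, (-pi, pi]) at spindle troughs."""

    phases: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.size and (
            np.any(self.phases <= -np.pi - 1e-9) or np.any(self.phases > np.pi + 1e-9)
        ):
            raise ValueError("phases must lie in (-pi, pi]")

    @property
    def n(self) -> int:
        return int(self.phases.size)


@dataclass(frozen=True)
class SpindleParams:
    """RMS-envelope detector parameters (all tunable in the run config)."""

    band: tuple[float, float] = SPINDLE_BAND
    rms_window_s: float = 0.2
    threshold_sd: float = 1.5
    min_dur_s: float = 0.5
    max_dur_s: float = 3.0
    merge_gap_s: float = 0.5


def _rms_envelope(filtered: np.ndarray, sampling_rate: float, window_s: float) -> np.ndarray:
    n = max(int(round(window_s * sampling_rate)), 1)
    # clip float error: the moving mean of squares can dip just below zero
    power = np.maximum(ndimage.uniform_filter1d(filtered**2, size=n, mode="nearest"), 0.0)
    return np.sqrt(power)


def detect_spindles(
    trace: np.ndarray,
    sampling_rate: float,
    n2_segments: StageSegments,
    params: SpindleParams = SpindleParams(),
    channel: str = "",
) -> list[SpindleEvent]:
    """Detect spindles on one bipolar trace within NREM-2 segments."""
    if "N2" not in n2_segments.stage.split("+"):
        raise ValueError("spindles are detected during NREM 2 segments only")
    fs = sampling_rate
    filtered = bandpass(np.asarray(trace, dtype=float), fs, *params.band)
    envelope = _rms_envelope(filtered, fs, params.rms_window_s)
    mask = n2_segments.sample_mask(len(filtered), fs)
    if not mask.any():
        return []
    threshold = envelope[mask].mean() + params.threshold_sd * envelope[mask].std()

    supra = (envelope > threshold) & mask
    edges = np.diff(supra.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if supra[0]:
        starts.insert(0, 0)
    if supra[-1]:
        ends.append(len(supra))

    # events are supra-threshold runs of qualifying duration; events closer
    # than the merge gap are then fused (if still within the maximum duration)
    qualifying = [
        [s, e]
        for s, e in zip(starts, ends)
        if params.min_dur_s <= (e - s) / fs <= params.max_dur_s
    ]
    merged: list[list[int]] = []
    gap = params.merge_gap_s * fs
    for s, e in qualifying:
        if merged and s - merged[-1][1] < gap and (e - merged[-1][0]) / fs <= params.max_dur_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        trough = s + int(np.argmin(filtered[s:e]))
        events.append(
            SpindleEvent(
                channel=channel,
                onset_s=s / fs,
                offset_s=e / fs,
                trough_time_s=trough / fs,
            )
        )
    return events


def spindle_features(
    events: list[SpindleEvent],
    trace: np.ndarray,
    sampling_rate: float,
    n2_segments: StageSegments,
    band: tuple[float, float] = SPINDLE_BAND,
    epoch_half_width_s: float = 3.0,
    central: str = "median",
) -> tuple[dict[str, float], list[SpindleEvent]]:
    """Spindle density, amplitude and duration for one channel.

    Amplitude is the max-minus-min range of the 11-16 Hz filtered +/-3 s
    epoch around each spindle's maximal trough.  Epochs reaching past a
    recording edge are truncated and flagged but still counted for density.
    Returns the summary dict and the events annotated with amplitudes.
    """
    minutes = n2_segments.total_minutes
    if minutes <= 0:
        raise ValueError("NREM-2 segments have zero duration")
    fs = sampling_rate
    trace = np.asarray(trace, dtype=float)
    filtered = bandpass(trace, fs, *band)
    half = int(round(epoch_half_width_s * fs))

    annotated: list[SpindleEvent] = []
    for ev in events:
        c = int(round(ev.trough_time_s * fs))
        lo, hi = c - half, c + half
        truncated = lo < 0 or hi > len(trace)
        epoch = filtered[max(lo, 0): min(hi, len(trace))]
        annotated.append(
            SpindleEvent(
                channel=ev.channel,
                onset_s=ev.onset_s,
                offset_s=ev.offset_s,
                trough_time_s=ev.trough_time_s,
                amplitude_uv=float(epoch.max() - epoch.min()),
                truncated_epoch=truncated,
            )
        )

    stat = {"median": np.median, "mean": np.mean}[central]
    summary = {
        "sp_density": len(events) / minutes,
        "sp_amplitude": float(stat([e.amplitude_uv for e in annotated]))
        if annotated
        else float("nan"),
        "sp_duration": float(stat([e.duration_s for e in annotated]))
        if annotated
        else float("nan"),
    }
    return summary, annotated


def slow_osc_phase_at_troughs(
    raw_trace: np.ndarray,
    sampling_rate: float,
    events: list[SpindleEvent],
    band: tuple[float, float] = DELTA_BAND,
    min_epoch_s: float = 1.0,
    epoch_half_width_s: float = 3.0,
) -> PhaseSet:
    """Slow-oscillation Hilbert phase at each spindle's maximal trough.

    The raw trace is filtered to the delta band and Hilbert-transformed; the
    instantaneous phase (cosine convention: 0 at a signal maximum, +/-pi at a
    trough) is read at each trough sample.  Events whose +/-3 s epoch is
    truncated below ``min_epoch_s`` are excluded and counted.
    """
    if not events:
        raise ValueError("no spindle events to phase-lock")
    fs = sampling_rate
    raw = np.asarray(raw_trace, dtype=float)
    filtered = bandpass(raw, fs, *band)
    phase = np.angle(hilbert(filtered))

    phases = []
    excluded = 0
    half = int(round(epoch_half_width_s * fs))
    min_len = int(round(min_epoch_s * fs))
    for ev in events:
        c = int(round(ev.trough_time_s * fs))
        lo, hi = max(c - half, 0), min(c + half, len(raw))
        if hi - lo < min_len or not (0 <= c < len(raw)):
            excluded += 1
            continue
        phases.append(phase[c])
    return PhaseSet(phases=np.array(phases), n_excluded=excluded)


def itc(phases: PhaseSet | np.ndarray) -> float:
    """Inter-trial coherence of a phase set: |mean of unit phase vectors|.

    Returns NaN (undefined) for an empty set rather than 0, since 0 is the
    meaningful asymptotic value for uniform phases.
    """
    phi = phases.phases if isinstance(phases, PhaseSet) else np.asarray(phases, float)
    if phi.size == 0:
        return float("nan")
    return float(np.abs(np.mean(np.exp(1j * phi))))
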