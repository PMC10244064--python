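"""Shared fixtures: tiny deterministic recordings and event traces."""

from __future__ import annotations

import numpy as np
import pytest

from sleepasym.eeg_io import Hypnogram, Recording, StageSegments


FS = 256.0


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_recording(labels, signal, fs=FS, sides=None):
    return Recording(
        channel_labels=list(labels),
        sampling_rate=fs,
        signal=np.asarray(signal, dtype=float),
        sides=sides,
    )


@pytest.fixture
def n2_hypnogram():
    """30 minutes of contiguous N2."""
    return Hypnogram([("N2", 0.0, 1800.0)])


def segments(intervals, stage="N2"):
    return StageSegments(stage=stage, intervals=list(intervals))


def inject_half_sine(trace, fs, onset_s, duration_s, amplitude_uv):
    """Add a negative half-sine (a slow-wave surrogate) in place."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / (n - 1)
    i0 = int(round(onset_s * fs))
    trace[i0: i0 + n] -= amplitude_uv * np.sin(np.pi * t)
    return trace


def inject_burst(trace, fs, centre_s, duration_s, amplitude_range_uv, freq_hz=13.0):
    """Add a Hann-windowed oscillatory burst whose minimum is at the centre."""
    n = int(round(duration_s * fs))
    if n % 2 == 0:
        n += 1
    t = (np.arange(n) - n // 2) / fs
    w = -(amplitude_range_uv / 2.0) * np.hanning(n) * np.cos(2 * np.pi * freq_hz * t)
    c = int(round(centre_s * fs))
    trace[c - n // 2: c - n // 2 + n] += w
    return trace
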