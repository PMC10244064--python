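"""Reading, referencing and staging of sleep EEG recordings.

Recordings are plain channels-by-samples arrays in microvolts with 10-20
electrode labels.  The module provides the extended longitudinal bipolar
montage with inferior temporal electrodes used for lateralized analyses,
average-reference derivation for the slow-wave cross-check, extraction of
scored NREM segments (minus an optional artifact mask), and pooling of
per-night feature tables.

EDF input goes through :func:`mne.io.read_raw_edf`; EDF output (needed by
the synthetic cohort writer) uses a small 16-bit EDF writer since the signal
content here is plain uniform-rate EEG.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "BipolarMontage",
    "Hypnogram",
    "StageSegments",
    "STANDARD_MONTAGE",
    "SW_CHANNELS",
    "SPINDLE_CHANNELS",
    "SPINDLE_PAIRS",
    "FEATURES",
    "IED_FEATURE",
    "normalize_label",
    "read_recording",
    "write_edf",
    "derive_bipolar",
    "derive_average_reference",
    "extract_segments",
    "pool_nights",
]

STAGES = ("W", "N1", "N2", "N3", "REM", "ART")

#: the nine sleep features analysed per hemisphere
FEATURES = (
    "delta_power",
    "sw_density",
    "sw_amplitude",
    "sw_duration",
    "sw_slope",
    "sp_density",
    "sp_amplitude",
    "sp_duration",
    "sp_locking",
)
IED_FEATURE = "ied_rate"

# old nomenclature -> modified combinatorial nomenclature
_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

_CANONICAL = (
    "Fp1 Fp2 F3 F4 F7 F8 F9 F10 FT9 FT10 C3 C4 T7 T8 P3 P4 P7 P8 P9 P10 "
    "O1 O2 Fz Cz Pz Oz Fpz A1 A2 M1 M2"
).split()
_CANON_UPPER = {name.upper(): name for name in _CANONICAL}


def normalize_label(raw: str) -> str:
    """Normalize an EDF channel label to its 10-20 electrode name.

    Strips ``EEG`` prefixes and reference suffixes (``Fp1-Ref`` -> ``Fp1``),
    resolves legacy aliases (``T3`` -> ``T7``) and canonicalizes case.
    Labels that do not look like 10-20 electrodes are returned stripped but
    otherwise untouched.
    """
    label = raw.strip()
    if label.upper().startswith("EEG "):
        label = label[4:].strip()
    for suffix in ("-Ref", "-REF", "-ref", "-LE", "-AVG"):
        if label.endswith(suffix):
            label = label[: -len(suffix)]
            break
    label = label.strip()
    upper = label.upper()
    upper = _ALIASES.get(upper, upper)
    return _CANON_UPPER.get(upper, _ALIASES.get(label.upper(), label))


@dataclass
class Recording:
    """A multichannel EEG signal in microvolts.

    ``sides`` optionally tags each channel as ``"left"``/``"right"``/``None``
    (used by bipolar derivations to keep hemisphere bookkeeping).
    """

    channel_labels: list[str]
    sampling_rate: float
    signal: np.ndarray  # channels x samples, microvolts
    start_time: float = 0.0
    sides: list[str | None] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per signal row required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.sides is not None and len(self.sides) != len(self.channel_labels):
            raise ValueError("one side tag per channel required")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def trace(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.signal[idx]


@dataclass(frozen=True)
class BipolarMontage:
    """Ordered anode/cathode pairs, each tagged with its hemisphere.

    The derived trace is anode minus cathode.  Midline electrodes are
    disallowed and the left and right pair sets must mirror each other,
    because every downstream statistic is a left/right contrast.
    """

    pairs: tuple[tuple[str, str], ...]
    sides: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.sides):
            raise ValueError("one side per pair required")
        midline = {"Fz", "Cz", "Pz", "Oz", "Fpz"}
        for anode, cathode in self.pairs:
            if anode in midline or cathode in midline:
                raise ValueError(f"midline electrode in pair {anode}-{cathode}")
        if set(self.sides) - {"left", "right"}:
            raise ValueError("sides must be 'left' or 'right'")
        left = {p for p, s in zip(self.pairs, self.sides) if s == "left"}
        right = {p for p, s in zip(self.pairs, self.sides) if s == "right"}
        if {(_mirror(a), _mirror(c)) for a, c in left} != right:
            raise ValueError("left and right pair sets are not mirror-symmetric")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.pairs]

    def electrodes(self) -> set[str]:
        return {e for pair in self.pairs for e in pair}


def _mirror(electrode: str) -> str:
    """Mirror a lateralized 10-20 electrode across the midline (F3 <-> F4)."""
    head = electrode.rstrip("0123456789")
    num = electrode[len(head):]
    if not num:
        return electrode
    n = int(num)
    return f"{head}{n - 1 if n % 2 == 0 else n + 1}"


def _standard_montage() -> BipolarMontage:
    right = [
        ("Fp2", "F10"), ("F10", "FT10"), ("FT10", "P10"), ("P10", "O2"),
        ("Fp2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
        ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ]
    left = [
        ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
        ("Fp1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
        ("Fp1", "F9"), ("F9", "FT9"), ("FT9", "P9"), ("P9", "O1"),
    ]
    return BipolarMontage(
        pairs=tuple(right + left),
        sides=tuple(["right"] * len(right) + ["left"] * len(left)),
    )


#: extended longitudinal bipolar montage with inferior temporal electrodes
STANDARD_MONTAGE = _standard_montage()

#: bipolar channels used for discrete slow-wave detection, per hemisphere
SW_CHANNELS = {"left": ("F3-C3", "F7-T7"), "right": ("F4-C4", "F8-T8")}

#: bipolar channels used for spindle detection, per hemisphere
SPINDLE_CHANNELS = {"left": "C3-FT9", "right": "C4-FT10"}
SPINDLE_PAIRS = BipolarMontage(
    pairs=(("C3", "FT9"), ("C4", "FT10")), sides=("left", "right")
)


@dataclass
class Hypnogram:
    """Scored sleep stages as (stage, onset_s, duration_s) epochs."""

    epochs: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for stage, onset, dur in self.epochs:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            if dur <= 0:
                raise ValueError("epoch durations must be positive")
        ordered = sorted(self.epochs, key=lambda e: e[1])
        for (_, o1, d1), (_, o2, _) in zip(ordered, ordered[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError("hypnogram epochs overlap")

    def total_s(self, stage: str) -> float:
        return sum(d for s, _, d in self.epochs if s == stage)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.epochs, columns=["stage", "onset_s", "duration_s"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Hypnogram":
        df = pd.read_csv(path)
        return cls(
            [
                (str(r.stage), float(r.onset_s), float(r.duration_s))
                for r in df.itertuples()
            ]
        )


@dataclass
class StageSegments:
    """Disjoint [onset, offset) intervals of one sleep stage, in seconds."""

    stage: str
    intervals: list[tuple[float, float]]
    below_minimum: bool = False  # < 20 min of scored data quality flag

    def __post_init__(self) -> None:
        for onset, offset in self.intervals:
            if offset <= onset:
                raise ValueError("empty or inverted interval")
        ordered = sorted(self.intervals)
        for (_, e1), (s2, _) in zip(ordered, ordered[1:]):
            if e1 > s2 + 1e-9:
                raise ValueError("segment intervals overlap")

    @property
    def total_minutes(self) -> float:
        return sum(e - s for s, e in self.intervals) / 60.0

    def slices(self, sampling_rate: float) -> list[slice]:
        return [
            slice(int(round(s * sampling_rate)), int(round(e * sampling_rate)))
            for s, e in self.intervals
        ]

    def sample_mask(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for sl in self.slices(sampling_rate):
            mask[max(sl.start, 0): min(sl.stop, n_samples)] = True
        return mask


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, required: Iterable[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    Channel labels are normalized to 10-20 names.  If ``required`` electrode
    names are given, missing ones raise a ``ValueError`` naming them.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    rates = {float(raw.info["sfreq"])}
    if len(rates) != 1:
        raise ValueError("mixed per-channel sampling rates are not supported")
    labels = [normalize_label(name) for name in raw.ch_names]
    signal = raw.get_data() * 1e6  # mne returns volts
    rec = Recording(
        channel_labels=labels,
        sampling_rate=float(raw.info["sfreq"]),
        signal=signal,
    )
    if required is not None:
        missing = sorted(set(required) - set(labels))
        if missing:
            raise ValueError(f"recording lacks required electrode(s): {', '.join(missing)}")
    return rec


def write_edf(rec: Recording, path: str | Path, patient_id: str = "X") -> None:
    """Write a :class:`Recording` to a plain 16-bit EDF file.

    One-second data records; the signal is zero-padded to a whole number of
    records.  Physical units are microvolts.
    """
    sfreq = rec.sampling_rate
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    ns = int(round(sfreq))
    n_ch = len(rec.channel_labels)
    n_rec = int(np.ceil(rec.n_samples / ns))
    data = np.zeros((n_ch, n_rec * ns))
    data[:, : rec.n_samples] = rec.signal

    pmins, pmaxs, digital = [], [], []
    for row in data:
        lim = max(np.max(np.abs(row)), 1.0) * 1.0001
        pmins.append(-lim)
        pmaxs.append(lim)
        digital.append(np.round(row / lim * 32767).astype("<i2"))

    def _f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _f("0", 8),
            _f(patient_id, 80),
            _f("synthetic sleep EEG", 80),
            _f(start.strftime("%d.%m.%y"), 8),
            _f(start.strftime("%H.%M.%S"), 8),
            _f(str(256 + 256 * n_ch), 8),
            _f("", 44),
            _f(str(n_rec), 8),
            _f("1", 8),
            _f(str(n_ch), 4),
        ]
    )
    header += b"".join(_f(lab, 16) for lab in rec.channel_labels)
    header += b"".join(_f("AgAgCl electrode", 80) for _ in range(n_ch))
    header += b"".join(_f("uV", 8) for _ in range(n_ch))
    header += b"".join(_f(f"{v:.4g}", 8) for v in pmins)
    header += b"".join(_f(f"{v:.4g}", 8) for v in pmaxs)
    header += b"".join(_f("-32768", 8) for _ in range(n_ch))
    header += b"".join(_f("32767", 8) for _ in range(n_ch))
    header += b"".join(_f("", 80) for _ in range(n_ch))
    header += b"".join(_f(str(ns), 8) for _ in range(n_ch))
    header += b"".join(_f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(digital[ch][r * ns: (r + 1) * ns].tobytes())


# ---------------------------------------------------------------------------
# Derivations
# ---------------------------------------------------------------------------

def derive_bipolar(rec: Recording, montage: BipolarMontage = STANDARD_MONTAGE) -> Recording:
    """Derive bipolar traces (anode minus cathode) with hemisphere tags."""
    missing = sorted(montage.electrodes() - set(rec.channel_labels))
    if missing:
        raise ValueError(f"recording lacks required electrode(s): {', '.join(missing)}")
    traces = np.vstack(
        [rec.trace(anode) - rec.trace(cathode) for anode, cathode in montage.pairs]
    )
    return Recording(
        channel_labels=montage.labels,
        sampling_rate=rec.sampling_rate,
        signal=traces,
        start_time=rec.start_time,
        sides=list(montage.sides),
    )


def derive_average_reference(
    rec: Recording, electrodes: Sequence[str] | None = None
) -> Recording:
    """Re-reference to the mean over ``electrodes`` (default: all channels)."""
    if electrodes is None:
        electrodes = rec.channel_labels
    if len(electrodes) < 2:
        raise ValueError("average reference needs at least two electrodes")
    ref = np.mean([rec.trace(e) for e in electrodes], axis=0)
    return Recording(
        channel_labels=list(rec.channel_labels),
        sampling_rate=rec.sampling_rate,
        signal=rec.signal - ref[None, :],
        start_time=rec.start_time,
        sides=rec.sides,
    )


# ---------------------------------------------------------------------------
# Stage segments
# ---------------------------------------------------------------------------

def _subtract_intervals(
    intervals: list[tuple[float, float]], holes: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    out = list(intervals)
    for h0, h1 in sorted(holes):
        nxt: list[tuple[float, float]] = []
        for s, e in out:
            if h1 <= s or h0 >= e:
                nxt.append((s, e))
                continue
            if h0 > s:
                nxt.append((s, h0))
            if h1 < e:
                nxt.append((h1, e))
        out = nxt
    return [iv for iv in out if iv[1] - iv[0] > 1e-9]


def extract_segments(
    rec: Recording,
    hyp: Hypnogram,
    stage: str | Sequence[str],
    artifact_mask: list[tuple[float, float]] | None = None,
    min_minutes: float = 20.0,
) -> StageSegments:
    """Extract scored intervals of one or more stages, minus artifact spans.

    Recordings with less than ``min_minutes`` of the requested stage are
    flagged (``below_minimum``) but still returned, so that the cohort
    assembler can enforce the >= 20 min inclusion rule where appropriate.
    """
    stages = (stage,) if isinstance(stage, str) else tuple(stage)
    intervals = sorted(
        (onset, onset + dur) for s, onset, dur in hyp.epochs if s in stages
    )
    if not intervals:
        raise ValueError(f"hypnogram contains no epochs of stage(s) {stages}")
    # merge adjacency, clip to recording
    merged: list[tuple[float, float]] = []
    for s, e in intervals:
        e = min(e, rec.duration_s)
        s = min(s, rec.duration_s)
        if e - s <= 1e-9:
            continue
        if merged and s <= merged[-1][1] + 1e-9:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    if artifact_mask:
        merged = _subtract_intervals(merged, list(artifact_mask))
    seg = StageSegments(stage="+".join(stages), intervals=merged)
    if seg.total_minutes < min_minutes:
        seg.below_minimum = True
        warnings.warn(
            f"only {seg.total_minutes:.1f} min of {seg.stage} scored "
            f"(< {min_minutes:g} min)",
            stacklevel=2,
        )
    return seg


# ---------------------------------------------------------------------------
# Night pooling
# ---------------------------------------------------------------------------

def pool_nights(*tables: pd.DataFrame) -> pd.DataFrame:
    """Average per-night hemispheric feature tables into pooled rows.

    Input tables have columns (patient_id, night, feature, value_left,
    value_right).  Patients present in a single night pass through with a
    ``single_night`` provenance flag.
    """
    frames = [t for t in tables if t is not None and len(t)]
    if not frames:
        raise ValueError("no feature tables to pool")
    stacked = pd.concat(frames, ignore_index=True)
    grouped = stacked.groupby(["patient_id", "feature"], sort=False).agg(
        value_left=("value_left", "mean"),
        value_right=("value_right", "mean"),
        n_nights=("night", "nunique"),
    )
    pooled = grouped.reset_index()
    pooled["night"] = "pooled"
    pooled["provenance"] = np.where(pooled.pop("n_nights") > 1, "both_nights", "single_night")
    return pooled[["patient_id", "night", "feature", "value_left", "value_right", "provenance"]]
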