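"""Synthetic sleep-EEG cohorts with known hemispheric asymmetries.

The generator emulates the statistical structure the analysis pipeline
assumes: 1/f Gaussian background EEG on a 10-20 electrode set, scored
N2/N3 blocks, negative half-sine slow waves, Hann-windowed 13 Hz spindle
bursts optionally phase-locked (von Mises) to a slow oscillation, biphasic
interictal-discharge-like transients, and configurable left/right asymmetry
of every feature.  Ground truth (the generative per-side parameter of every
feature and its lateralization index) is emitted alongside the signals, so
every stage of the pipeline can be tested for parameter recovery without any
real recording.

Asymmetries are parameterized directly as the target lateralization index l
of each feature: the left/right generative values are m(1+l) and m(1-l)
around a bilateral base value m, which realizes LI = l exactly.  Power-like
features (delta) scale amplitude gains by sqrt(1 +/- l).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0, i1

from .eeg_io import FEATURES, IED_FEATURE, Hypnogram, Recording, write_edf

__all__ = [
    "SideParams",
    "NightPlan",
    "PatientSpec",
    "CohortSpec",
    "Cohort",
    "FOCAL_PROFILE",
    "DEFAULT_ELECTRODES",
    "expected_itc",
    "kappa_for_itc",
    "mirror_patient",
    "simulate_night",
    "simulate_cohort",
    "make_feature_matrix_from_truth",
]

#: 22 lateralized electrodes of the extended longitudinal montage + midline
DEFAULT_ELECTRODES = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "F9", "F10", "FT9", "FT10",
    "C3", "C4", "T7", "T8", "P3", "P4", "P7", "P8", "P9", "P10",
    "O1", "O2", "Fz", "Cz", "Pz",
)

_LEFT_OF = {
    "Fp1": "Fp2", "F3": "F4", "F7": "F8", "F9": "F10", "FT9": "FT10",
    "C3": "C4", "T7": "T8", "P3": "P4", "P7": "P8", "P9": "P10", "O1": "O2",
}

# spatial gain of each event type on same-side electrodes (left convention;
# mirrored for right).  Slow waves ride the fronto-temporal chains so the
# longitudinal derivation keeps most of the deflection; the coherent slow
# oscillation is put with equal gain on F3/C3/P3 so it cancels on the
# slow-wave detection pairs but survives on the spindle channel C3-FT9.
_SW_GAINS = {"F3": 1.0, "F7": 1.0, "C3": 0.25, "T7": 0.25}
_SP_GAINS = {"C3": 1.0}
_SO_GAINS = {"F3": 1.0, "C3": 1.0, "P3": 1.0}
_IED_GAINS = {"F7": 1.0, "T7": 0.8, "FT9": 0.6}


def expected_itc(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution: I1(k)/I0(k)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def kappa_for_itc(r: float) -> float:
    """Invert the von Mises concentration for a target mean resultant length."""
    if not 0 <= r < 1:
        raise ValueError("target ITC must be in [0, 1)")
    if r == 0:
        return 0.0
    return float(brentq(lambda k: expected_itc(k) - r, 1e-6, 500.0))


@dataclass(frozen=True)
class SideParams:
    """Generative per-hemisphere parameters of every sleep feature."""

    sw_rate_per_min: float = 6.0
    sw_amplitude_uv: float = 75.0
    sw_duration_bounds_s: tuple[float, float] = (0.4, 0.8)
    sp_rate_per_min: float = 1.5
    sp_amplitude_uv: float = 30.0
    sp_duration_s: float = 1.0
    coupling_kappa: float = 1.0
    delta_gain: float = 1.0
    ied_rate_per_min: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sw_rate_per_min, self.sp_rate_per_min, self.ied_rate_per_min) < 0:
            raise ValueError("rates must be non-negative")
        if self.coupling_kappa < 0:
            raise ValueError("kappa must be non-negative")
        if min(self.sw_amplitude_uv, self.sp_amplitude_uv, self.delta_gain) <= 0:
            raise ValueError("amplitudes and gains must be positive")

    def truth(self) -> dict[str, float]:
        """Expected per-hemisphere value of each feature (proportional units)."""
        dur = float(np.mean(self.sw_duration_bounds_s))
        return {
            "delta_power": self.delta_gain**2,
            "sw_density": self.sw_rate_per_min,
            "sw_amplitude": self.sw_amplitude_uv,
            "sw_duration": dur,
            # half-sine trough sits at mid-duration, so slope = a / (d/2)
            "sw_slope": self.sw_amplitude_uv / (dur / 2.0),
            "sp_density": self.sp_rate_per_min,
            "sp_amplitude": self.sp_amplitude_uv,
            "sp_duration": self.sp_duration_s,
            "sp_locking": expected_itc(self.coupling_kappa),
            IED_FEATURE: self.ied_rate_per_min,
        }


@dataclass(frozen=True)
class NightPlan:
    """Stage schedule of one simulated night as (stage, duration_s) blocks."""

    blocks: tuple[tuple[str, float], ...] = (("N2", 600.0), ("N3", 600.0))

    def total_s(self) -> float:
        return sum(d for _, d in self.blocks)

    def hypnogram(self) -> Hypnogram:
        epochs = []
        t = 0.0
        for stage, dur in self.blocks:
            epochs.append((stage, t, dur))
            t += dur
        return Hypnogram(epochs)

    def stage_intervals(self, stages: tuple[str, ...]) -> list[tuple[float, float]]:
        out = []
        t = 0.0
        for stage, dur in self.blocks:
            if stage in stages:
                out.append((t, t + dur))
            t += dur
        return out


@dataclass(frozen=True)
class PatientSpec:
    """Everything needed to simulate one patient's nights reproducibly."""

    patient_id: str
    epileptic_side: str  # "left" | "right"
    left: SideParams = SideParams()
    right: SideParams = SideParams()
    nights: tuple[NightPlan, ...] = (NightPlan(),)
    noise_beta: float = 1.0
    noise_sd_uv: float = 12.0
    so_freq_hz: float = 0.75
    so_amplitude_uv: float = 12.0
    spindle_freq_hz: float = 13.0
    ied_amplitude_uv: float = 60.0
    sampling_rate: float = 256.0
    electrodes: tuple[str, ...] = DEFAULT_ELECTRODES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epileptic_side not in ("left", "right"):
            raise ValueError("epileptic_side must be 'left' or 'right'")
        if not 0 <= self.noise_beta <= 2:
            raise ValueError("noise 1/f exponent must be in [0, 2]")

    def truth_table(self) -> pd.DataFrame:
        lt, rt = self.left.truth(), self.right.truth()
        rows = []
        for feat in (*FEATURES, IED_FEATURE):
            vl, vr = lt[feat], rt[feat]
            total = vl + vr
            li = (vl - vr) / total if total > 0 else np.nan
            rows.append(
                {
                    "patient_id": self.patient_id,
                    "feature": feat,
                    "truth_left": vl,
                    "truth_right": vr,
                    "truth_li": li,
                }
            )
        return pd.DataFrame(rows)


def mirror_patient(spec: PatientSpec) -> PatientSpec:
    """Swap the left/right generative parameters (and the focus label)."""
    return replace(
        spec,
        left=spec.right,
        right=spec.left,
        epileptic_side="right" if spec.epileptic_side == "left" else "left",
    )


# ---------------------------------------------------------------------------
# Night simulation
# ---------------------------------------------------------------------------

def _pink_noise(
    rng: np.random.Generator,
    n: int,
    sfreq: float,
    beta: float,
    sd: float,
    delta_gain: float,
) -> np.ndarray:
    """1/f^beta Gaussian noise; the 0.5-4 Hz band scaled by ``delta_gain``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-beta / 2.0)
    shape[0] = 0.0
    shape[(freqs >= 0.5) & (freqs <= 4.0)] *= delta_gain
    x = np.fft.irfft(spec * shape, n=n)
    # normalize so the unscaled (delta_gain = 1) process has SD ``sd``
    ref = np.ones_like(freqs)
    ref[nz] = freqs[nz] ** (-beta / 2.0)
    ref[0] = 0.0
    base_sd = np.sqrt(np.mean(ref**2))
    return x * (sd / base_sd)


def _half_sine(amplitude: float, duration_s: float, sfreq: float) -> np.ndarray:
    n = max(int(round(duration_s * sfreq)), 2)
    t = np.arange(n) / (n - 1)
    return -amplitude * np.sin(np.pi * t)


def _spindle_burst(
    amplitude_range: float, duration_s: float, carrier_hz: float, sfreq: float
) -> np.ndarray:
    """Hann-windowed carrier whose minimum sits at the burst centre."""
    n = max(int(round(duration_s * sfreq)), 2)
    if n % 2 == 0:
        n += 1
    t = (np.arange(n) - n // 2) / sfreq
    window = np.hanning(n)
    return -(amplitude_range / 2.0) * window * np.cos(2 * np.pi * carrier_hz * t)


def _ied_waveform(amplitude: float, sfreq: float, width_s: float = 0.07) -> np.ndarray:
    """Biphasic sharp transient (derivative-of-Gaussian spike surrogate)."""
    n = max(int(round(width_s * sfreq)), 4)
    t = np.linspace(-1.0, 1.0, n)
    w = -t * np.exp(-4 * t**2)
    return amplitude * w / np.max(np.abs(w))


def _place_events(
    rng: np.random.Generator,
    intervals: list[tuple[float, float]],
    rate_per_min: float,
    duration_fn,
    occupied: list[tuple[float, float]],
    max_attempts: int = 100,
) -> list[tuple[float, float]]:
    """Draw non-overlapping (onset, duration) placements inside intervals."""
    total_min = sum(e - s for s, e in intervals) / 60.0
    n_target = rng.poisson(rate_per_min * total_min) if rate_per_min > 0 else 0
    weights = np.array([e - s for s, e in intervals], dtype=float)
    weights /= weights.sum() if weights.sum() else 1.0
    placed = []
    margin = 0.05
    for _ in range(n_target):
        for _attempt in range(max_attempts):
            dur = float(duration_fn())
            k = rng.choice(len(intervals), p=weights)
            s, e = intervals[k]
            if e - s <= dur + 2 * margin:
                continue
            onset = rng.uniform(s + margin, e - dur - margin)
            span = (onset - margin, onset + dur + margin)
            if all(span[1] <= o0 or span[0] >= o1 for o0, o1 in occupied):
                occupied.append(span)
                placed.append((onset, dur))
                break
    return placed


def simulate_night(
    spec: PatientSpec, night_idx: int = 0
) -> tuple[Recording, Hypnogram, dict]:
    """Simulate one night of multichannel EEG for a patient.

    Returns the recording (microvolts), the hypnogram, and a ground-truth
    dict with the injected event placements and counts per hemisphere.
    """
    plan = spec.nights[night_idx]
    sfreq = spec.sampling_rate
    n = int(round(plan.total_s() * sfreq))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, night_idx]))

    side_params = {"left": spec.left, "right": spec.right}
    signal = np.zeros((len(spec.electrodes), n))
    ch_index = {e: i for i, e in enumerate(spec.electrodes)}

    def _side_of(electrode: str) -> str | None:
        if electrode in _LEFT_OF:
            return "left"
        if electrode in _LEFT_OF.values():
            return "right"
        return None

    # 1/f background, delta band scaled per hemisphere
    for e, i in ch_index.items():
        side = _side_of(e)
        if side is None:
            gain = float(np.mean([spec.left.delta_gain, spec.right.delta_gain]))
        else:
            gain = side_params[side].delta_gain
        signal[i] = _pink_noise(rng, n, sfreq, spec.noise_beta, spec.noise_sd_uv, gain)

    # coherent slow oscillation (the phase reference spindles lock to)
    theta0 = {s: rng.uniform(-np.pi, np.pi) for s in ("left", "right")}
    tt = np.arange(n) / sfreq
    so_phase = {s: 2 * np.pi * spec.so_freq_hz * tt + theta0[s] for s in ("left", "right")}
    for side in ("left", "right"):
        so = (
            spec.so_amplitude_uv
            * side_params[side].delta_gain
            * np.cos(so_phase[side])
        )
        for e_left, gain in _SO_GAINS.items():
            e = e_left if side == "left" else _LEFT_OF[e_left]
            signal[ch_index[e]] += gain * so

    nrem = plan.stage_intervals(("N2", "N3"))
    n2 = plan.stage_intervals(("N2",))
    truth: dict = {"night_idx": night_idx}

    def _add(electrode_gains: dict[str, float], side: str, onset: float, wave: np.ndarray):
        i0_ = int(round(onset * sfreq))
        for e_left, gain in electrode_gains.items():
            e = e_left if side == "left" else _LEFT_OF[e_left]
            seg = signal[ch_index[e], i0_: i0_ + len(wave)]
            seg += gain * wave[: len(seg)]

    for side in ("left", "right"):
        params = side_params[side]
        occupied: list[tuple[float, float]] = []

        # slow waves over N2+N3
        lo, hi = params.sw_duration_bounds_s
        sw = _place_events(
            rng, nrem, params.sw_rate_per_min, lambda: rng.uniform(lo, hi), occupied
        )
        for onset, dur in sw:
            _add(_SW_GAINS, side, onset, _half_sine(params.sw_amplitude_uv, dur, sfreq))

        # spindles over N2, troughs phase-locked to the slow oscillation
        if params.sp_rate_per_min > 0 and n2:
            sp_candidates = _place_events(
                rng, n2, params.sp_rate_per_min, lambda: params.sp_duration_s, occupied
            )
            spindles = []
            for onset, dur in sp_candidates:
                centre = onset + dur / 2.0
                if params.coupling_kappa > 0:
                    phi = rng.vonmises(np.pi, params.coupling_kappa)
                    cur = (
                        2 * np.pi * spec.so_freq_hz * centre + theta0[side]
                    )
                    shift = ((phi - cur + np.pi) % (2 * np.pi) - np.pi) / (
                        2 * np.pi * spec.so_freq_hz
                    )
                    centre = centre + shift
                    onset = centre - dur / 2.0
                    # keep within its N2 interval
                    k = next(
                        (i for i, (s, e) in enumerate(n2) if s <= centre <= e), None
                    )
                    if k is None or onset < n2[k][0] or onset + dur > n2[k][1]:
                        continue
                burst = _spindle_burst(
                    params.sp_amplitude_uv, dur, spec.spindle_freq_hz, sfreq
                )
                _add(_SP_GAINS, side, onset, burst)
                spindles.append((onset, dur))
            truth[f"sp_events_{side}"] = spindles
        else:
            truth[f"sp_events_{side}"] = []

        # interictal-discharge-like transients over the whole night
        ied = _place_events(
            rng,
            [(0.0, plan.total_s())],
            params.ied_rate_per_min,
            lambda: 0.07,
            occupied,
        )
        for onset, _dur in ied:
            _add(_IED_GAINS, side, onset, _ied_waveform(spec.ied_amplitude_uv, sfreq))

        truth[f"sw_events_{side}"] = sw
        truth[f"n_sw_{side}"] = len(sw)
        truth[f"n_sp_{side}"] = len(truth[f"sp_events_{side}"])
        truth[f"n_ied_{side}"] = len(ied)

    rec = Recording(
        channel_labels=list(spec.electrodes),
        sampling_rate=sfreq,
        signal=signal,
    )
    return rec, plan.hypnogram(), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: per-feature (median LI in the LEFT-focus group, between-patient SD),
#: typical of a left-focus group: delta power, slow-wave
#: amplitude/slope and spindle amplitude higher on the epileptic side;
#: spindle density lower; IED rate much higher on the epileptic side.
FOCAL_PROFILE: dict[str, tuple[float, float]] = {
    "delta_power": (0.05, 0.18),
    "sw_density": (0.0, 0.15),
    "sw_amplitude": (0.04, 0.16),
    "sw_duration": (0.0, 0.10),
    "sw_slope": (0.05, 0.16),
    "sp_density": (-0.07, 0.13),
    "sp_amplitude": (0.05, 0.20),
    "sp_duration": (0.0, 0.10),
    "sp_locking": (0.0, 0.10),
    IED_FEATURE: (0.5, 0.35),
}

#: bilateral base value of each feature used to turn a target LI into
#: left/right generative parameters
BASE_VALUES = {
    "delta_power": 1.0,  # squared gain; the physical scale sits in noise_sd_uv
    "sw_density": 6.0,
    "sw_amplitude": 75.0,
    "sw_duration": 0.6,
    "sp_density": 1.5,
    "sp_amplitude": 30.0,
    "sp_duration": 1.0,
    "sp_locking": 0.4,
    IED_FEATURE: 1.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Group-level recipe from which per-patient asymmetries are drawn."""

    n_left: int = 34
    n_right: int = 34
    profile: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(FOCAL_PROFILE)
    )
    base_values: dict[str, float] = field(default_factory=lambda: dict(BASE_VALUES))
    nights: tuple[NightPlan, ...] = (NightPlan(),)
    master_seed: int = 0
    patient_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_left < 1 or self.n_right < 1:
            raise ValueError("both groups need at least one patient")
        for feat, (med, _sd) in self.profile.items():
            if not -1 < med < 1:
                raise ValueError(f"target LI for {feat} must be in (-1, 1)")


@dataclass
class Cohort:
    """A simulated cohort: specs, labels and the ground-truth table."""

    patients: list[PatientSpec]
    truth: pd.DataFrame
    spec: CohortSpec

    @property
    def labels(self) -> dict[str, str]:
        return {p.patient_id: p.epileptic_side for p in self.patients}


def _draw_patient_lis(
    rng: np.random.Generator, profile: dict, group_sign: float
) -> dict[str, float]:
    out = {}
    for feat, (median, sd) in profile.items():
        li = group_sign * median + rng.normal(0.0, sd)
        out[feat] = float(np.clip(li, -0.95, 0.95))
    return out


def _params_from_lis(lis: dict[str, float], base: dict[str, float]) -> tuple[SideParams, SideParams]:
    def lr(feat: str) -> tuple[float, float]:
        m, l = base[feat], lis.get(feat, 0.0)
        return m * (1 + l), m * (1 - l)

    swr = lr("sw_density")
    swa = lr("sw_amplitude")
    swd = lr("sw_duration")
    spr = lr("sp_density")
    spa = lr("sp_amplitude")
    spd = lr("sp_duration")
    dp = lr("delta_power")
    lock = lr("sp_locking")
    ied = lr(IED_FEATURE)

    def side(i: int) -> SideParams:
        d = swd[i]
        return SideParams(
            sw_rate_per_min=swr[i],
            sw_amplitude_uv=swa[i],
            sw_duration_bounds_s=(d * 2 / 3, d * 4 / 3),
            sp_rate_per_min=spr[i],
            sp_amplitude_uv=spa[i],
            sp_duration_s=spd[i],
            coupling_kappa=kappa_for_itc(min(lock[i], 0.99)),
            delta_gain=float(np.sqrt(dp[i])),
            ied_rate_per_min=ied[i],
        )

    return side(0), side(1)


def simulate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Draw per-patient asymmetries, build patient specs and ground truth.

    If ``out_dir`` is given, signals are simulated and written as one EDF and
    one hypnogram CSV per patient-night, plus a truth-table TSV; otherwise
    the cohort is returned spec-only (nights can be simulated on demand with
    :func:`simulate_night`).
    """
    rng = np.random.default_rng(spec.master_seed)
    patients = []
    truth_frames = []
    for group, count in (("left", spec.n_left), ("right", spec.n_right)):
        sign = 1.0 if group == "left" else -1.0
        for i in range(count):
            pid = f"{group[0].upper()}{i + 1:03d}"
            lis = _draw_patient_lis(rng, spec.profile, sign)
            left, right = _params_from_lis(lis, spec.base_values)
            patient = PatientSpec(
                patient_id=pid,
                epileptic_side=group,
                left=left,
                right=right,
                nights=spec.nights,
                seed=int(rng.integers(0, 2**31 - 1)),
                **spec.patient_kwargs,
            )
            patients.append(patient)
            truth_frames.append(patient.truth_table())
    truth = pd.concat(truth_frames, ignore_index=True)
    truth["group"] = truth["patient_id"].str[0].map({"L": "left", "R": "right"})
    cohort = Cohort(patients=patients, truth=truth, spec=spec)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ied_rows = []
        for patient in patients:
            for night_idx in range(len(patient.nights)):
                rec, hyp, night_truth = simulate_night(patient, night_idx)
                stem = out / f"{patient.patient_id}_night{night_idx + 1}"
                write_edf(rec, stem.with_suffix(".edf"), patient_id=patient.patient_id)
                hyp.to_csv(stem.with_suffix(".hypnogram.csv"))
                ied_rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "night": night_idx + 1,
                        "count_left": night_truth["n_ied_left"],
                        "count_right": night_truth["n_ied_right"],
                        "minutes": patient.nights[night_idx].total_s() / 60.0,
                    }
                )
        pd.DataFrame(ied_rows).to_csv(out / "ied_counts.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"patient_id": list(cohort.labels), "group": list(cohort.labels.values())}
        ).to_csv(out / "labels.tsv", sep="\t", index=False)
    return cohort


def make_feature_matrix_from_truth(
    spec: CohortSpec, seed: int | None = None, with_ied: bool = True
) -> pd.DataFrame:
    """Sample a per-patient LI feature matrix directly from the generative
    distributions (no signal synthesis) for fast classifier testing."""
    rng = np.random.default_rng(spec.master_seed if seed is None else seed)
    features = list(FEATURES) + ([IED_FEATURE] if with_ied else [])
    rows = []
    index = []
    for group, count in (("left", spec.n_left), ("right", spec.n_right)):
        sign = 1.0 if group == "left" else -1.0
        for i in range(count):
            lis = _draw_patient_lis(rng, spec.profile, sign)
            row = {f: lis.get(f, 0.0) for f in features}
            row["label"] = group
            rows.append(row)
            index.append(f"{group[0].upper()}{i + 1:03d}")
    return pd.DataFrame(rows, index=index)
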