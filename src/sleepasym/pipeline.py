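"""End-to-end orchestration: per-patient feature extraction to cohort reports.

One night of one patient runs: EDF -> bipolar + average-referenced
derivations -> scored N2/N3 segments -> delta power (N2+N3), slow waves
(N2+N3) and spindles with slow-oscillation locking (N2 only) -> one row per
feature with a left and a right hemisphere value.  Nights are averaged per
patient for the group statistics; the classifier consumes night-1 values
only, for clinical applicability (a single recorded night), unless
overridden.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asymmetry_stats as stats
from . import classification as clf
from .eeg_io import (
    FEATURES,
    IED_FEATURE,
    STANDARD_MONTAGE,
    SPINDLE_CHANNELS,
    SPINDLE_PAIRS,
    SW_CHANNELS,
    Hypnogram,
    Recording,
    derive_average_reference,
    derive_bipolar,
    extract_segments,
    pool_nights,
    read_recording,
)
from .slow_activity import compute_delta_power, detect_slow_waves, summarize_slow_waves
from .spindles import (
    SpindleParams,
    detect_spindles,
    itc,
    slow_osc_phase_at_troughs,
    spindle_features,
)

__all__ = ["RunConfig", "extract_patient_features", "run_full_study"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable analysis parameters, with round-trippable YAML I/O."""

    seed: int = 0
    # staging
    min_stage_minutes: float = 20.0
    # slow activity
    delta_band: tuple[float, float] = (0.5, 4.0)
    welch_window_s: float = 4.0
    sw_min_dur_s: float = 0.25
    sw_max_dur_s: float = 1.0
    sw_min_amplitude_uv: float | None = None
    sw_filter_order: int = 4
    central: str = "median"
    # spindles
    spindle_band: tuple[float, float] = (11.0, 16.0)
    spindle_rms_window_s: float = 0.2
    spindle_threshold_sd: float = 1.5
    spindle_min_dur_s: float = 0.5
    spindle_max_dur_s: float = 3.0
    spindle_merge_gap_s: float = 0.5
    # classification
    n_iterations: int = 5000
    k_folds: int = 5
    classifier_night: int | str = 1  # night whose LIs feed the decision tree
    output_dir: str | None = None

    def spindle_params(self) -> SpindleParams:
        return SpindleParams(
            band=tuple(self.spindle_band),
            rms_window_s=self.spindle_rms_window_s,
            threshold_sd=self.spindle_threshold_sd,
            min_dur_s=self.spindle_min_dur_s,
            max_dur_s=self.spindle_max_dur_s,
            merge_gap_s=self.spindle_merge_gap_s,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["delta_band"] = list(self.delta_band)
        data["spindle_band"] = list(self.spindle_band)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["delta_band"] = tuple(data["delta_band"])
        data["spindle_band"] = tuple(data["spindle_band"])
        return cls(**data)


def extract_night_features(
    rec: Recording,
    hyp: Hypnogram,
    config: RunConfig,
    patient_id: str,
    night: int,
    artifact_mask: list[tuple[float, float]] | None = None,
    ied_counts: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Run the full per-night feature extraction; one row per feature."""
    bipolar = derive_bipolar(rec, STANDARD_MONTAGE)
    avgref = derive_average_reference(rec)
    nrem = extract_segments(
        rec, hyp, ("N2", "N3"), artifact_mask, min_minutes=config.min_stage_minutes
    )
    n2 = extract_segments(
        rec, hyp, "N2", artifact_mask, min_minutes=config.min_stage_minutes
    )

    values: dict[str, dict[str, float]] = {}

    delta = compute_delta_power(
        bipolar, nrem, band=config.delta_band, window_s=config.welch_window_s
    )
    values["delta_power"] = delta.hemisphere_power

    sw_events = detect_slow_waves(
        bipolar,
        avgref,
        nrem,
        band=config.delta_band,
        min_dur_s=config.sw_min_dur_s,
        max_dur_s=config.sw_max_dur_s,
        min_amplitude_uv=config.sw_min_amplitude_uv,
        filter_order=config.sw_filter_order,
    )
    sw_summary = summarize_slow_waves(sw_events, nrem, central=config.central)
    for feat in ("sw_density", "sw_amplitude", "sw_duration", "sw_slope"):
        values[feat] = {side: sw_summary[side][feat] for side in ("left", "right")}

    sp_bipolar = derive_bipolar(rec, SPINDLE_PAIRS)
    params = config.spindle_params()
    for side in ("left", "right"):
        label = SPINDLE_CHANNELS[side]
        trace = sp_bipolar.trace(label)
        events = detect_spindles(trace, rec.sampling_rate, n2, params, channel=label)
        summary, annotated = spindle_features(
            events,
            trace,
            rec.sampling_rate,
            n2,
            band=params.band,
            central=config.central,
        )
        for feat in ("sp_density", "sp_amplitude", "sp_duration"):
            values.setdefault(feat, {})[side] = summary[feat]
        if annotated:
            phases = slow_osc_phase_at_troughs(
                trace, rec.sampling_rate, annotated, band=config.delta_band
            )
            values.setdefault("sp_locking", {})[side] = itc(phases)
        else:
            values.setdefault("sp_locking", {})[side] = float("nan")

    if ied_counts is not None:
        minutes = rec.duration_s / 60.0
        values[IED_FEATURE] = {
            "left": ied_counts[0] / minutes,
            "right": ied_counts[1] / minutes,
        }

    rows = [
        {
            "patient_id": patient_id,
            "night": night,
            "feature": feat,
            "value_left": vals.get("left", float("nan")),
            "value_right": vals.get("right", float("nan")),
        }
        for feat, vals in values.items()
    ]
    return pd.DataFrame(rows)


def extract_patient_features(
    recordings: list[Recording],
    hypnograms: list[Hypnogram],
    config: RunConfig,
    patient_id: str = "patient",
    artifact_masks: list[list[tuple[float, float]] | None] | None = None,
    ied_counts: list[tuple[float, float] | None] | None = None,
) -> pd.DataFrame:
    """Per-night hemispheric feature table plus pooled (night-averaged) rows."""
    if not recordings:
        raise ValueError("at least one night is required")
    if len(recordings) != len(hypnograms):
        raise ValueError("one hypnogram per recording is required")
    nights = []
    for idx, (rec, hyp) in enumerate(zip(recordings, hypnograms)):
        mask = artifact_masks[idx] if artifact_masks else None
        ied = ied_counts[idx] if ied_counts else None
        try:
            nights.append(
                extract_night_features(
                    rec, hyp, config, patient_id, idx + 1,
                    artifact_mask=mask, ied_counts=ied,
                )
            )
        except Exception as err:
            raise RuntimeError(
                f"feature extraction failed for {patient_id} night {idx + 1}: {err}"
            ) from err
    pooled = pool_nights(*nights)
    return pd.concat(nights + [pooled], ignore_index=True)


def _feature_matrix_from_table(
    table: pd.DataFrame,
    groups: dict[str, str],
    night: int | str,
    features: list[str],
) -> pd.DataFrame:
    records = stats.build_lateralization_records(table, groups, night=night)
    wide = records.pivot(index="patient_id", columns="feature", values="li")
    missing = [f for f in features if f not in wide.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    matrix = wide[features].dropna()
    matrix["label"] = matrix.index.map(groups)
    return matrix


def run_full_study(
    cohort_dir: str | Path,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the complete study on a cohort directory.

    Expects ``<patient>_night<k>.edf`` + ``.hypnogram.csv`` pairs, a
    ``labels.tsv`` (patient_id, group) and optionally ``ied_counts.tsv``.
    Produces group statistics on pooled nights, night-stability checks,
    the paired hemisphere contrast, and the classifier battery (sleep-only,
    shuffle null, and when IEDs are available IED-only and sleep+IED), all
    written to ``out_dir`` with the config and seed for provenance.
    """
    cohort_dir = Path(cohort_dir)
    labels_df = pd.read_csv(cohort_dir / "labels.tsv", sep="\t")
    groups = dict(zip(labels_df["patient_id"].astype(str), labels_df["group"]))

    ied_path = cohort_dir / "ied_counts.tsv"
    ied_df = pd.read_csv(ied_path, sep="\t") if ied_path.exists() else None

    tables = []
    for pid in groups:
        stage = f"load {pid}"
        try:
            recs, hyps, ieds = [], [], []
            for night in (1, 2, 3):
                edf = cohort_dir / f"{pid}_night{night}.edf"
                if not edf.exists():
                    break
                recs.append(read_recording(edf))
                hyps.append(Hypnogram.from_csv(cohort_dir / f"{pid}_night{night}.hypnogram.csv"))
                if ied_df is not None:
                    row = ied_df[(ied_df.patient_id == pid) & (ied_df.night == night)]
                    ieds.append(
                        (float(row.count_left.iloc[0]), float(row.count_right.iloc[0]))
                        if len(row)
                        else None
                    )
            if not recs:
                raise FileNotFoundError(f"no nights found for patient {pid}")
            stage = f"extract {pid}"
            tables.append(
                extract_patient_features(
                    recs, hyps, config, patient_id=pid,
                    ied_counts=ieds if ied_df is not None else None,
                )
            )
        except Exception as err:
            raise RuntimeError(f"study aborted at stage '{stage}': {err}") from err

    table = pd.concat(tables, ignore_index=True)
    report: dict = {"n_patients": len(groups)}

    records = stats.build_lateralization_records(table, groups, night="pooled")
    report["group_compare"] = stats.group_compare(records)
    if (table["night"] == 2).any():
        report["night_stability"] = stats.night_stability(table, groups)
    report["paired_sp_density"] = stats.paired_hemisphere_compare(
        table, "sp_density", groups
    )

    sleep_feats = list(FEATURES)
    matrix = _feature_matrix_from_table(
        table, groups, config.classifier_night, sleep_feats
    )
    runs = {
        "sleep": clf.run_repeated_cv(
            matrix, n_iter=config.n_iterations, k=config.k_folds,
            seed=config.seed, feature_names=sleep_feats,
        ),
        "shuffle": clf.run_shuffle_null(
            matrix, n_iter=config.n_iterations, k=config.k_folds,
            seed=config.seed + 1, feature_names=sleep_feats,
        ),
    }
    has_ied = ied_df is not None and (table["feature"] == IED_FEATURE).any()
    if has_ied:
        full_matrix = _feature_matrix_from_table(
            table, groups, config.classifier_night, sleep_feats + [IED_FEATURE]
        )
        runs["ied"] = clf.run_repeated_cv(
            full_matrix, n_iter=config.n_iterations, k=config.k_folds,
            seed=config.seed + 2, feature_names=[IED_FEATURE],
        )
        runs["sleep+ied"] = clf.run_repeated_cv(
            full_matrix, n_iter=config.n_iterations, k=config.k_folds,
            seed=config.seed + 3, feature_names=sleep_feats + [IED_FEATURE],
        )
        report["low_asymmetry_subset"] = clf.low_asymmetry_subset(
            full_matrix, n_iter=min(config.n_iterations, 500),
            k=config.k_folds, seed=config.seed + 4,
        )
    report["runs"] = runs
    report["compare"] = clf.compare_runs(*runs.values(), names=list(runs))
    report["fisher_p"] = clf.contingency_significance(runs["sleep"])
    report["importance"] = clf.predictor_importance(runs["sleep"])
    report["feature_table"] = table

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        table.to_csv(out / "feature_table.tsv", sep="\t", index=False)
        report["group_compare"].to_csv(out / "group_compare.tsv", sep="\t", index=False)
        if "night_stability" in report:
            report["night_stability"].to_csv(
                out / "night_stability.tsv", sep="\t", index=False
            )
        report["compare"].to_csv(out / "classifier_compare.tsv", sep="\t", index=False)
        report["importance"].to_frame().to_csv(out / "importance.tsv", sep="\t")
        summary = {
            "seed": config.seed,
            "fisher_p": report["fisher_p"],
            "paired_sp_density": {
                k: v for k, v in report["paired_sp_density"].items()
                if isinstance(v, (int, float, str, bool))
            },
            "runs": {name: run.summary() for name, run in runs.items()},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return report
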