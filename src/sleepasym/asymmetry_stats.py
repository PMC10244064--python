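"""Lateralization indices and group-level nonparametric statistics.

Every per-hemisphere feature X is reduced to one value per patient, the
lateralization index

    LI = (X_left - X_right) / (X_left + X_right),

bounded in [-1, 1] for non-negative features.  Patients with a left versus a
right epileptic focus are then compared feature by feature: Mann-Whitney for
delta power (a family of one) and Kruskal-Wallis + Dunn's multiple-comparison
correction within the slow-wave and spindle feature families.  Effect sizes
are the probability of superiority.  Night-to-night stability and paired
epileptic-versus-non-epileptic hemisphere contrasts use Wilcoxon signed-rank
tests.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "lateralization_index",
    "build_lateralization_records",
    "probability_of_superiority",
    "mann_whitney",
    "dunn_test",
    "group_compare",
    "night_stability",
    "paired_hemisphere_compare",
    "DEFAULT_FAMILIES",
]

logger = logging.getLogger(__name__)

#: multiple-comparison families mirroring the per-figure structure:
#: delta power alone; four slow-wave features; four spindle features.
DEFAULT_FAMILIES = {
    "delta": ("delta_power",),
    "slow_waves": ("sw_density", "sw_amplitude", "sw_duration", "sw_slope"),
    "spindles": ("sp_density", "sp_amplitude", "sp_duration", "sp_locking"),
}


def lateralization_index(x_left, x_right):
    """LI = (left - right) / (left + right) for non-negative magnitudes.

    Vectorized; returns NaN where both sides are zero (undefined), raises on
    negative input since every analysed feature is a magnitude, density,
    duration or coherence.
    """
    xl = np.asarray(x_left, dtype=float)
    xr = np.asarray(x_right, dtype=float)
    if np.any(xl < 0) or np.any(xr < 0):
        raise ValueError("lateralization index is defined for non-negative magnitudes")
    total = xl + xr
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(total > 0, (xl - xr) / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(x_left) and np.isscalar(x_right):
        return float(li)
    return li


def build_lateralization_records(
    table: pd.DataFrame, groups: dict[str, str], night: str | int = "pooled"
) -> pd.DataFrame:
    """Per-patient LI records from a hemispheric feature table.

    ``groups`` maps patient_id to ``"left"``/``"right"`` focus.  Rows with an
    undefined LI (both hemispheres zero, or a NaN feature) are dropped
    pairwise with a logged count.
    """
    sub = table[table["night"] == night].copy()
    sub["li"] = lateralization_index(sub["value_left"].values, sub["value_right"].values)
    n_undefined = int(sub["li"].isna().sum())
    if n_undefined:
        logger.info("dropping %d undefined LI rows", n_undefined)
    sub = sub.dropna(subset=["li"])
    sub["group"] = sub["patient_id"].map(groups)
    if sub["group"].isna().any():
        missing = sorted(sub.loc[sub["group"].isna(), "patient_id"].unique())
        raise ValueError(f"no focus label for patient(s): {missing}")
    return sub[["patient_id", "feature", "li", "group"]].reset_index(drop=True)


def probability_of_superiority(x_left_group, x_right_group) -> float:
    """Nonparametric effect size: P(draw from A > draw from B), ties half.

    ES = [#(a > b) + 0.5 #(a = b)] / (len(a) * len(b)) over all pairs.
    """
    a = np.asarray(x_left_group, dtype=float)
    b = np.asarray(x_right_group, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float((gt + 0.5 * eq) / (a.size * b.size))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    return (a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum()


def mann_whitney(a, b, max_exact: int = 100_000) -> dict:
    """Two-sided Mann-Whitney U test.

    Small samples (number of group assignments <= ``max_exact``) use the
    exact permutation distribution of U (handles ties); larger samples the
    tie-corrected normal approximation with continuity correction.  Two-sided
    p is P(|U - n1 n2 / 2| >= |u - n1 n2 / 2|) under the exact null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(a, b)
    es = u / (n1 * n2)
    if comb(n1 + n2, n1) <= max_exact:
        pooled = np.concatenate([a, b])
        centre = n1 * n2 / 2.0
        observed = abs(u - centre)
        hits = total = 0
        idx = np.arange(n1 + n2)
        for pick in combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(pick)] = True
            u_p = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u_p - centre) >= observed - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        _, p = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
        method = "asymptotic"
    return {"u": float(u), "p": float(p), "es": float(es), "method": method}


def dunn_test(samples: dict[str, np.ndarray], comparisons: list[tuple[str, str]]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z-tests with tie correction.

    All samples are pooled and ranked once; each requested comparison gets a
    z statistic and a Bonferroni-style family adjustment over the number of
    comparisons (adjusted p capped at 1), the convention of common
    Kruskal-Wallis + Dunn implementations.
    """
    names = list(samples)
    values = np.concatenate([np.asarray(samples[k], float) for k in names])
    sizes = {k: len(samples[k]) for k in names}
    n = len(values)
    ranks = sst.rankdata(values)
    mean_ranks = {}
    pos = 0
    for k in names:
        mean_ranks[k] = ranks[pos: pos + sizes[k]].mean()
        pos += sizes[k]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    m = len(comparisons)
    rows = []
    for i, j in comparisons:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sst.norm.sf(abs(z))
        rows.append(
            {
                "group_a": i,
                "group_b": j,
                "z": float(z),
                "p_raw": float(p),
                "p_adj": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    records: pd.DataFrame,
    families: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Compare LI between left- and right-focus groups, feature by feature.

    Delta power (family of one) uses the Mann-Whitney test; the slow-wave
    and spindle families use a Kruskal-Wallis omnibus over group x feature
    followed by Dunn's post hoc on the left-versus-right contrast within
    each feature, adjusted within the family.  The probability-of-superiority
    effect size is attached to every contrast.
    """
    if families is None:
        families = DEFAULT_FAMILIES
    for grp in ("left", "right"):
        n = records.loc[records["group"] == grp, "patient_id"].nunique()
        if n < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 patients")

    def li_of(feature: str, group: str) -> np.ndarray:
        sel = (records["feature"] == feature) & (records["group"] == group)
        return records.loc[sel, "li"].to_numpy()

    rows = []
    for family, feats in families.items():
        if len(feats) == 1:
            feat = feats[0]
            a, b = li_of(feat, "left"), li_of(feat, "right")
            res = mann_whitney(a, b)
            rows.append(
                {
                    "family": family,
                    "feature": feat,
                    "test": f"mann-whitney ({res['method']})",
                    "statistic": res["u"],
                    "p_raw": res["p"],
                    "p_adj": res["p"],
                    "es": probability_of_superiority(a, b),
                }
            )
            continue
        samples = {}
        for feat in feats:
            samples[f"{feat}|left"] = li_of(feat, "left")
            samples[f"{feat}|right"] = li_of(feat, "right")
        h_stat, kw_p = sst.kruskal(*samples.values())
        posthoc = dunn_test(
            samples, [(f"{f}|left", f"{f}|right") for f in feats]
        ).set_index("group_a")
        for feat in feats:
            ph = posthoc.loc[f"{feat}|left"]
            a, b = samples[f"{feat}|left"], samples[f"{feat}|right"]
            rows.append(
                {
                    "family": family,
                    "feature": feat,
                    "test": "kruskal-wallis + dunn",
                    "statistic": ph["z"],
                    "p_raw": ph["p_raw"],
                    "p_adj": ph["p_adj"],
                    "es": probability_of_superiority(a, b),
                    "kw_h": float(h_stat),
                    "kw_p": float(kw_p),
                }
            )
    return pd.DataFrame(rows)


def _wilcoxon(diff: np.ndarray) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank on precomputed differences.

    All-zero differences are the degenerate no-change case: statistic 0,
    p = 1 marker.
    """
    diff = np.asarray(diff, dtype=float)
    nz = diff[diff != 0]
    if nz.size == 0:
        return 0.0, 1.0
    method = "exact" if nz.size <= 25 and len(np.unique(np.abs(nz))) == nz.size else "approx"
    res = sst.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def night_stability(table: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Within-group paired comparison of each feature's LI across two nights.

    For every feature and focus group, a two-sided Wilcoxon signed-rank test
    of night-1 versus night-2 LI over patients with both nights.  Fewer than
    5 complete pairs flags the test as underpowered (still computed).
    """
    rows = []
    per_night = {}
    for night in (1, 2):
        sub = table[table["night"] == night].copy()
        if sub.empty:
            raise ValueError(f"table contains no night-{night} rows")
        sub[f"li{night}"] = lateralization_index(
            sub["value_left"].values, sub["value_right"].values
        )
        per_night[night] = sub[["patient_id", "feature", f"li{night}"]]
    merged = per_night[1].merge(per_night[2], on=["patient_id", "feature"]).dropna()
    merged["group"] = merged["patient_id"].map(groups)
    for (group, feature), block in merged.groupby(["group", "feature"]):
        diff = (block["li2"] - block["li1"]).to_numpy()
        stat, p = _wilcoxon(diff)
        rows.append(
            {
                "group": group,
                "feature": feature,
                "n_pairs": len(diff),
                "statistic": stat,
                "p": p,
                "underpowered": len(diff) < 5,
            }
        )
    return pd.DataFrame(rows)


def paired_hemisphere_compare(
    table: pd.DataFrame,
    feature: str,
    groups: dict[str, str],
    night: str | int = "pooled",
) -> dict:
    """Paired raw-value contrast: epileptic versus non-epileptic hemisphere.

    Re-labels each patient's (left, right) values to (epileptic,
    non-epileptic) using the focus label and runs a two-sided Wilcoxon
    signed-rank test; reports medians and interquartile ranges per side.
    """
    sub = table[(table["night"] == night) & (table["feature"] == feature)]
    epi, non = [], []
    for row in sub.itertuples():
        side = groups.get(row.patient_id)
        if side is None:
            raise ValueError(f"no focus label for patient {row.patient_id}")
        if side == "left":
            epi.append(row.value_left)
            non.append(row.value_right)
        else:
            epi.append(row.value_right)
            non.append(row.value_left)
    epi = np.asarray(epi, float)
    non = np.asarray(non, float)
    keep = ~(np.isnan(epi) | np.isnan(non))
    epi, non = epi[keep], non[keep]
    stat, p = _wilcoxon(epi - non)
    q = lambda x: (float(np.percentile(x, 25)), float(np.percentile(x, 75)))
    return {
        "feature": feature,
        "n_pairs": int(epi.size),
        "statistic": stat,
        "p": p,
        "median_epileptic": float(np.median(epi)) if epi.size else float("nan"),
        "iqr_epileptic": q(epi) if epi.size else (float("nan"),) * 2,
        "median_non_epileptic": float(np.median(non)) if non.size else float("nan"),
        "iqr_non_epileptic": q(non) if non.size else (float("nan"),) * 2,
        "underpowered": epi.size < 5,
    }
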