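"""Lateralization indices and nonparametric group statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from sleepasym.asymmetry_stats import (
    build_lateralization_records,
    dunn_test,
    group_compare,
    lateralization_index,
    mann_whitney,
    night_stability,
    paired_hemisphere_compare,
    probability_of_superiority,
)


# ---------------------------------------------------------------- LI

def test_li_examples():
    assert lateralization_index(5.0, 5.0) == 0.0
    assert lateralization_index(2.0, 0.0) == 1.0
    assert lateralization_index(0.0, 2.0) == -1.0
    assert lateralization_index(1.40, 1.61) == pytest.approx(-0.0698, abs=1e-4)


def test_li_undefined_when_both_zero():
    assert np.isnan(lateralization_index(0.0, 0.0))


def test_li_rejects_negative_magnitudes():
    with pytest.raises(ValueError):
        lateralization_index(-1.0, 2.0)


def test_li_antisymmetry_and_bounds(rng):
    left = rng.uniform(0, 10, 200)
    right = rng.uniform(0, 10, 200)
    li = lateralization_index(left, right)
    np.testing.assert_allclose(li, -lateralization_index(right, left), atol=1e-12)
    assert np.all(np.abs(li) <= 1.0)


def test_li_scale_invariance(rng):
    left = rng.uniform(0.1, 10, 50)
    right = rng.uniform(0.1, 10, 50)
    np.testing.assert_allclose(
        lateralization_index(7.0 * left, 7.0 * right),
        lateralization_index(left, right),
        atol=1e-12,
    )


def test_build_records_drops_undefined_rows():
    table = pd.DataFrame(
        [
            {"patient_id": "p1", "night": "pooled", "feature": "sw_density",
             "value_left": 4.0, "value_right": 2.0},
            {"patient_id": "p2", "night": "pooled", "feature": "sw_density",
             "value_left": 0.0, "value_right": 0.0},
            {"patient_id": "p3", "night": "pooled", "feature": "sw_density",
             "value_left": np.nan, "value_right": 1.0},
        ]
    )
    rec = build_lateralization_records(table, {"p1": "left", "p2": "left", "p3": "right"})
    assert list(rec["patient_id"]) == ["p1"]
    assert rec["li"].iloc[0] == pytest.approx(1.0 / 3.0)


# ---------------------------------------------------------------- effect size

def test_probability_of_superiority_examples():
    assert probability_of_superiority([1.0], [1.0]) == 0.5
    assert probability_of_superiority([2.0, 3.0], [0.0, 1.0]) == 1.0
    assert probability_of_superiority([1.0, 2.0], [1.0, 3.0]) == 0.375


def test_probability_of_superiority_duality(rng):
    a = rng.normal(size=12)
    b = rng.normal(size=9)
    assert probability_of_superiority(a, b) == pytest.approx(
        1.0 - probability_of_superiority(b, a)
    )


def test_effect_size_is_u_over_n1n2(rng):
    a = rng.normal(size=10)
    b = rng.normal(size=8)
    u, _ = sst.mannwhitneyu(a, b, alternative="two-sided")
    assert probability_of_superiority(a, b) == pytest.approx(u / (10 * 8))


# ---------------------------------------------------------------- Mann-Whitney

def _exact_p_oracle(a, b):
    """Brute-force permutation p for the centred two-sided U test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(a) + len(b)
    centre = n1 * (n - n1) / 2.0

    def u_stat(x, y):
        return (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()

    obs = abs(u_stat(a, b) - centre)
    hits = total = 0
    for pick in combinations(range(n), n1):
        sel = np.zeros(n, bool)
        sel[list(pick)] = True
        total += 1
        if abs(u_stat(pooled[sel], pooled[~sel]) - centre) >= obs - 1e-12:
            hits += 1
    return hits / total


def test_mann_whitney_fully_separated_small_groups():
    res = mann_whitney([0.4, 0.5, 0.6], [-0.6, -0.5, -0.4])
    assert res["method"] == "exact"
    assert res["p"] == pytest.approx(0.1)
    assert res["es"] == 1.0


def test_mann_whitney_matches_enumeration_oracle(rng):
    for _ in range(5):
        a = rng.normal(size=int(rng.integers(3, 7)))
        b = rng.normal(size=int(rng.integers(3, 7)))
        res = mann_whitney(a, b)
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(_exact_p_oracle(a, b))


def test_mann_whitney_handles_ties(rng):
    a = rng.integers(0, 3, size=6).astype(float)
    b = rng.integers(0, 3, size=5).astype(float)
    res = mann_whitney(a, b)
    assert res["p"] == pytest.approx(_exact_p_oracle(a, b))
    assert res["es"] == pytest.approx(probability_of_superiority(a, b))


def test_mann_whitney_identical_samples_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney(x, x)
    assert res["p"] == pytest.approx(1.0)
    assert res["es"] == 0.5


def test_mann_whitney_large_samples_use_asymptotic(rng):
    a = rng.normal(0.0, 1.0, 60)
    b = rng.normal(0.8, 1.0, 60)
    res = mann_whitney(a, b)
    assert res["method"] == "asymptotic"
    _, p_ref = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert res["p"] == pytest.approx(float(p_ref))


# ---------------------------------------------------------------- Dunn

def test_dunn_adjusted_never_below_raw(rng):
    samples = {k: rng.normal(i * 0.3, 1.0, 15) for i, k in enumerate("abcd")}
    comps = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")]
    out = dunn_test(samples, comps)
    assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
    assert (out["p_adj"] <= 1.0).all()


def test_dunn_bonferroni_factor_is_comparison_count(rng):
    samples = {k: rng.normal(i * 0.5, 1.0, 12) for i, k in enumerate("abc")}
    comps = [("a", "b"), ("a", "c"), ("b", "c")]
    out = dunn_test(samples, comps)
    for _, row in out.iterrows():
        assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 3))


def test_dunn_detects_clear_shift(rng):
    samples = {
        "x|left": rng.normal(2.0, 0.3, 20),
        "x|right": rng.normal(-2.0, 0.3, 20),
    }
    out = dunn_test(samples, [("x|left", "x|right")])
    assert out["p_adj"].iloc[0] < 1e-6
    assert out["z"].iloc[0] > 0


# ---------------------------------------------------------------- group compare

def _records(rng, shift=0.0, n=20):
    rows = []
    feats = ["delta_power", "sw_density", "sw_amplitude", "sw_duration",
             "sw_slope", "sp_density", "sp_amplitude", "sp_duration", "sp_locking"]
    for g, s in (("left", shift), ("right", -shift)):
        for i in range(n):
            for f in feats:
                rows.append({"patient_id": f"{g}{i}", "feature": f,
                             "li": rng.normal(s, 0.1), "group": g})
    return pd.DataFrame(rows)


def test_group_compare_null_is_nonsignificant(rng):
    out = group_compare(_records(rng, shift=0.0))
    assert len(out) == 9
    assert (out["p_adj"] > 0.05).sum() >= 8  # allow one 5% false positive
    assert out["es"].between(0.2, 0.8).all()


def test_group_compare_detects_global_shift(rng):
    out = group_compare(_records(rng, shift=0.3))
    assert (out["p_adj"] < 0.01).all()
    assert (out["es"] > 0.9).all()


def test_group_compare_family_structure(rng):
    out = group_compare(_records(rng))
    fam = out.set_index("feature")["family"]
    assert fam["delta_power"] == "delta"
    assert fam["sw_slope"] == "slow_waves"
    assert fam["sp_locking"] == "spindles"
    assert out.set_index("feature").loc["delta_power", "test"].startswith("mann-whitney")


def test_group_compare_requires_two_patients_per_group(rng):
    records = _records(rng).query("group == 'left' or patient_id == 'right0'")
    with pytest.raises(ValueError):
        group_compare(records)


# ---------------------------------------------------------------- stability

def _two_night_table(rng, n=12, shift=0.0):
    rows = []
    for i in range(n):
        base = rng.normal(0.0, 0.1)
        for night in (1, 2):
            li = base + (shift if night == 2 else 0.0) + rng.normal(0, 0.02)
            rows.append({"patient_id": f"p{i}", "night": night,
                         "feature": "sw_density",
                         "value_left": 1.0 + li, "value_right": 1.0 - li})
    return pd.DataFrame(rows)


def test_night_stability_stable_cohort(rng):
    table = _two_night_table(rng)
    out = night_stability(table, {f"p{i}": "left" for i in range(12)})
    assert len(out) == 1
    assert out["p"].iloc[0] > 0.05
    assert not out["underpowered"].iloc[0]


def test_night_stability_detects_systematic_shift(rng):
    table = _two_night_table(rng, shift=0.3)
    out = night_stability(table, {f"p{i}": "left" for i in range(12)})
    assert out["p"].iloc[0] < 0.01


def test_night_stability_identical_nights_p_one():
    rows = []
    for i in range(6):
        for night in (1, 2):
            rows.append({"patient_id": f"p{i}", "night": night,
                         "feature": "sw_density",
                         "value_left": 2.0 + i, "value_right": 1.0})
    out = night_stability(pd.DataFrame(rows), {f"p{i}": "left" for i in range(6)})
    assert out["p"].iloc[0] == 1.0


def test_night_stability_flags_few_pairs(rng):
    table = _two_night_table(rng, n=3)
    out = night_stability(table, {f"p{i}": "left" for i in range(3)})
    assert out["underpowered"].iloc[0]


def test_night_stability_requires_both_nights(rng):
    table = _two_night_table(rng)
    with pytest.raises(ValueError):
        night_stability(table[table["night"] == 1], {})


# ---------------------------------------------------------------- paired compare

def _hemi_table(deficit):
    rows = []
    for i in range(10):
        left = 2.0 - (deficit if i < 5 else 0.0)   # first 5 = left focus
        right = 2.0 - (deficit if i >= 5 else 0.0)  # last 5 = right focus
        rows.append({"patient_id": f"p{i}", "night": "pooled",
                     "feature": "sp_density",
                     "value_left": left + 0.01 * i, "value_right": right})
    return pd.DataFrame(rows)


def test_paired_hemisphere_detects_epileptic_deficit():
    groups = {f"p{i}": ("left" if i < 5 else "right") for i in range(10)}
    out = paired_hemisphere_compare(_hemi_table(0.5), "sp_density", groups)
    assert out["n_pairs"] == 10
    assert out["median_epileptic"] < out["median_non_epileptic"]
    assert out["p"] < 0.05


def test_paired_hemisphere_symmetric_is_nonsignificant(rng):
    table = _hemi_table(0.0)
    groups = {f"p{i}": ("left" if i < 5 else "right") for i in range(10)}
    out = paired_hemisphere_compare(table, "sp_density", groups)
    assert out["p"] > 0.05
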