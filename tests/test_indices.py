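"""Dietary index scoring against hand-computed and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from diet2gut import (
    compute_dii,
    compute_dqi,
    compute_hei,
    compute_mmds,
    load_dii_effects,
    load_dqi_rubric,
    load_hei_standards,
    load_mmds_config,
    standardize_scores,
)
from diet2gut.indices import mmds_max


# ---------------------------------------------------------------- DII ----


def _toy_intake(effects, values_by_param):
    """Intake table with every DII parameter present; unlisted parameters
    sit at a common positive constant (zero contribution needs variation,
    so tests vary only the listed ones)."""
    n = len(next(iter(values_by_param.values())))
    data = {p: np.full(n, 10.0) for p in effects.index}
    data.update({p: np.asarray(v, dtype=float) for p, v in values_by_param.items()})
    return pd.DataFrame(data, index=[f"s{i}" for i in range(n)])


def test_dii_zero_at_cohort_mean_and_mirror_antisymmetry():
    effects = load_dii_effects()
    varied = {p: [1.0, 3.0, 2.0] for p in ["fiber", "energy", "total_fat"]}
    intake = _toy_intake(effects, varied)
    # constant parameters carry zero SD in cohort mode -> restrict to varied
    eff = effects.loc[list(varied)]
    dii = compute_dii(intake[list(varied)], effects=eff, mode="cohort")["dii"]
    # s2 sits exactly at the cohort mean of every parameter
    assert dii["s2"] == pytest.approx(0.0, abs=1e-12)
    # s0 and s1 mirror about the mean: 2*Phi(z)-1 is odd in z
    assert dii["s0"] == pytest.approx(-dii["s1"], abs=1e-12)


def test_dii_matches_stepwise_oracle():
    """3 subjects x 3 parameters against an independent z -> Phi -> 2Phi-1 ->
    weighted-sum evaluation."""
    scores = {"a": 0.5, "b": -0.3, "c": 0.1}
    effects = pd.DataFrame(
        {"effect_score": scores, "ref_mean": 1.0, "ref_sd": 1.0, "unit": "g/day"}
    )
    intake = pd.DataFrame(
        {"a": [1.0, 2.0, 6.0], "b": [4.0, 1.0, 1.0], "c": [0.5, 0.5, 2.0]},
        index=["s0", "s1", "s2"],
    )
    got = compute_dii(intake, effects=effects, mode="cohort")["dii"]
    for subj in intake.index:
        total = 0.0
        for p in intake.columns:
            x = intake[p]
            z = (x[subj] - x.mean()) / x.std(ddof=0)
            pct = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
            total += (2.0 * pct - 1.0) * scores[p]
        assert got[subj] == pytest.approx(total, abs=1e-12)


def test_dii_global_mode_monotone_in_positive_effect_parameter():
    effects = load_dii_effects()
    base = _toy_intake(effects, {"saturated_fat": [10.0, 10.0]})
    more = base.copy()
    more.loc["s1", "saturated_fat"] = 40.0  # positive effect score
    assert effects.loc["saturated_fat", "effect_score"] > 0
    d0 = compute_dii(base, effects=effects, mode="global")["dii"]
    d1 = compute_dii(more, effects=effects, mode="global")["dii"]
    assert d1["s1"] > d0["s1"]
    assert d1["s0"] == pytest.approx(d0["s0"])


def test_dii_permutation_equivariance_and_errors(cohort):
    intake = cohort["intake"]
    dii = compute_dii(intake)["dii"]
    perm = intake.sample(frac=1.0, random_state=0)
    dii_perm = compute_dii(perm)["dii"]
    pd.testing.assert_series_equal(dii_perm.sort_index(), dii.sort_index())

    with pytest.raises(ValueError, match="missing DII parameter"):
        compute_dii(intake.drop(columns=["fiber"]))
    bad = intake.copy()
    bad.iloc[0, bad.columns.get_loc("fiber")] = -1.0
    with pytest.raises(ValueError, match="negative intake"):
        compute_dii(bad)
    flat = intake.copy()
    flat["fiber"] = 5.0
    with pytest.raises(ValueError, match="fiber"):
        compute_dii(flat, mode="cohort")


# --------------------------------------------------------------- MMDS ----


def _mmds_tables(values):
    cfg = load_mmds_config()
    groups = pd.DataFrame(
        {c: values[c] for c in cfg["beneficial"] if c != "fat_ratio"}
        | {c: values[c] for c in cfg["reverse_coded"]},
        index=[f"s{i}" for i in range(len(values["vegetables"]))],
    )
    intake = pd.DataFrame(
        {"mufa": values["mufa"], "pufa": values["pufa"],
         "saturated_fat": values["saturated_fat"], "alcohol": values["alcohol"]},
        index=groups.index,
    )
    return groups, intake, cfg


def test_mmds_extremes_hit_zero_and_configured_maximum():
    # s0: above all beneficial medians, below all reverse-coded, alcohol in
    # range; s3 is the exact opposite
    values = {
        "vegetables": [4, 1, 2, 0.5], "legumes": [2, 0.5, 1, 0.1],
        "fruit_nuts": [5, 2, 3, 1], "fish_seafood": [2, 0.5, 1, 0.1],
        "cereals": [6, 2, 4, 1], "meat": [0.1, 1, 0.5, 2],
        "meat_products": [0.1, 1, 0.5, 2], "dairy": [0.5, 2, 1, 3],
        "mufa": [30, 10, 15, 5], "pufa": [20, 5, 10, 2],
        "saturated_fat": [10, 20, 15, 30], "alcohol": [10, 40, 30, 0],
    }
    groups, intake, cfg = _mmds_tables(values)
    res = compute_mmds(groups, intake)
    assert res.loc["s0", "mmds"] == mmds_max(cfg) == 10
    assert res.loc["s3", "mmds"] == 0


def test_mmds_matches_exhaustive_hand_scoring():
    values = {
        "vegetables": [4, 1, 2, 3], "legumes": [0.1, 0.5, 1, 0.2],
        "fruit_nuts": [5, 2, 3, 2.5], "fish_seafood": [0.3, 0.5, 1, 0.1],
        "cereals": [6, 2, 4, 3], "meat": [0.5, 1, 0.4, 2],
        "meat_products": [0.2, 1, 0.5, 0.1], "dairy": [0.5, 2, 1, 3],
        "mufa": [30, 10, 15, 20], "pufa": [20, 5, 10, 8],
        "saturated_fat": [10, 20, 15, 12], "alcohol": [10, 40, 5, 26],
    }
    groups, intake, cfg = _mmds_tables(values)
    res = compute_mmds(groups, intake)
    ratio = (intake["mufa"] + intake["pufa"]) / intake["saturated_fat"]
    for subj in groups.index:
        expected = 0
        for comp in cfg["beneficial"]:
            col = ratio if comp == "fat_ratio" else groups[comp]
            expected += int(col[subj] > col.median())
        for comp in cfg["reverse_coded"]:
            expected += int(groups[comp][subj] < groups[comp].median())
        lo, hi = cfg["alcohol_range"]
        expected += int(lo <= intake["alcohol"][subj] <= hi)
        assert res.loc[subj, "mmds"] == expected
    assert res["mmds"].dtype.kind == "i"


def test_mmds_invariant_to_monotone_component_transform():
    values = {
        "vegetables": [4, 1, 2, 3], "legumes": [0.1, 0.5, 1, 0.2],
        "fruit_nuts": [5, 2, 3, 2.5], "fish_seafood": [0.3, 0.5, 1, 0.1],
        "cereals": [6, 2, 4, 3], "meat": [0.5, 1, 0.4, 2],
        "meat_products": [0.2, 1, 0.5, 0.1], "dairy": [0.5, 2, 1, 3],
        "mufa": [30, 10, 15, 20], "pufa": [20, 5, 10, 8],
        "saturated_fat": [10, 20, 15, 12], "alcohol": [10, 40, 5, 26],
    }
    groups, intake, _ = _mmds_tables(values)
    base = compute_mmds(groups, intake)["mmds"]
    transformed = groups.copy()
    transformed["vegetables"] = groups["vegetables"] ** 3  # strictly monotone
    transformed["meat"] = np.log1p(groups["meat"])
    assert (compute_mmds(transformed, intake)["mmds"] == base).all()


def test_mmds_zero_sfa_error_names_subject():
    values = {
        "vegetables": [4, 1], "legumes": [0.1, 0.5], "fruit_nuts": [5, 2],
        "fish_seafood": [0.3, 0.5], "cereals": [6, 2], "meat": [0.5, 1],
        "meat_products": [0.2, 1], "dairy": [0.5, 2], "mufa": [30, 10],
        "pufa": [20, 5], "saturated_fat": [0, 20], "alcohol": [10, 40],
    }
    groups, intake, _ = _mmds_tables(values)
    with pytest.raises(ValueError, match="s0"):
        compute_mmds(groups, intake)


# ---------------------------------------------------------------- HEI ----


def hei_profiles():
    """Perfect-scoring and worst-scoring intake/food-group profiles under the
    packaged standards (energy 2,000 kcal)."""
    standards = load_hei_standards()
    energy = 2000.0
    best_g, worst_g = {}, {}
    for comp, row in standards.iterrows():
        if row["basis"] != "per_1000kcal" or row["source"] == "sodium_g":
            continue
        if row["type"] == "adequacy":
            best_g[row["source"]] = row["std_max"] * energy / 1000.0
            worst_g[row["source"]] = 0.0
        else:
            best_g[row["source"]] = 0.0
            worst_g[row["source"]] = 2 * row["std_min"] * energy / 1000.0
    best_intake = {
        "energy": energy, "saturated_fat": 10.0, "mufa": 15.0, "pufa": 15.0,
        "sodium": 2000.0, "added_sugars": 20.0,
    }
    worst_intake = {
        "energy": energy, "saturated_fat": 60.0, "mufa": 5.0, "pufa": 5.0,
        "sodium": 6000.0, "added_sugars": 200.0,
    }
    groups = pd.DataFrame([best_g, worst_g], index=["best", "worst"])
    intake = pd.DataFrame([best_intake, worst_intake], index=["best", "worst"])
    return groups, intake


def test_hei_perfect_and_worst_profiles():
    groups, intake = hei_profiles()
    res = compute_hei(groups, intake)
    comp_cols = [c for c in res.columns if c != "hei"]
    assert len(comp_cols) == 13
    assert res.loc["best", "hei"] == pytest.approx(100.0)
    assert res.loc["worst", "hei"] == pytest.approx(0.0)
    assert ((res[comp_cols] >= 0).all() & (res[comp_cols] <= 10).all()).all()
    assert np.allclose(res["hei"], res[comp_cols].sum(axis=1))


def test_hei_halfway_density_earns_half_points():
    groups, intake = hei_profiles()
    standards = load_hei_standards()
    # whole_grains: adequacy, 10 points, max standard 1.5/1000 kcal
    half = standards.loc["whole_grains", "std_max"] / 2 * 2000.0 / 1000.0
    groups.loc["best", "whole_grains"] = half
    res = compute_hei(groups, intake)
    assert res.loc["best", "whole_grains"] == pytest.approx(5.0)
    assert res.loc["best", "hei"] == pytest.approx(95.0)


def test_hei_validation_errors():
    groups, intake = hei_profiles()
    bad = intake.copy()
    bad.loc["best", "energy"] = 0.0
    with pytest.raises(ValueError, match="energy"):
        compute_hei(groups, bad)
    standards = load_hei_standards().copy()
    standards.loc["whole_grains", "max_points"] = 5
    with pytest.raises(ValueError, match="sum to 100"):
        compute_hei(groups, intake, standards=standards)


# ---------------------------------------------------------------- DQI ----


def dqi_profiles():
    """Max-scoring and zero-scoring profiles under the packaged rubric."""
    best_groups = {
        "vegetables": 3.0, "fruit_nuts": 3.0, "cereals": 6.0, "legumes": 0.5,
        "fish_seafood": 0.6, "dairy": 1.0, "meat": 0.1,
        "empty_calorie_foods": 0.1,
    }
    best_intake = {
        "energy": 2000.0, "fiber": 30.0, "protein": 80.0, "iron": 18.0,
        "calcium": 1200.0, "vitamin_c": 90.0, "total_fat": 50.0,
        "saturated_fat": 10.0, "mufa": 10.0, "pufa": 7.5,
        "cholesterol": 100.0, "sodium": 1500.0, "carbohydrate": 287.5,
    }
    worst_groups = {
        "vegetables": 0.0, "fruit_nuts": 0.0, "cereals": 0.0, "legumes": 0.0,
        "fish_seafood": 0.0, "dairy": 0.0, "meat": 0.0,
        "empty_calorie_foods": 3.0,
    }
    worst_intake = {
        "energy": 2000.0, "fiber": 0.0, "protein": 0.0, "iron": 0.0,
        "calcium": 0.0, "vitamin_c": 0.0, "total_fat": 100.0,
        "saturated_fat": 40.0, "mufa": 80.0, "pufa": 80.0,
        "cholesterol": 500.0, "sodium": 4500.0, "carbohydrate": 0.0,
    }
    groups = pd.DataFrame([best_groups, worst_groups], index=["best", "worst"])
    intake = pd.DataFrame([best_intake, worst_intake], index=["best", "worst"])
    return groups, intake


def test_dqi_extremes_and_rubric_structure():
    groups, intake = dqi_profiles()
    rubric = load_dqi_rubric()
    assert rubric["max_points"].sum() == 100
    assert set(rubric["max_points"]) <= {3, 5, 6}
    res = compute_dqi(groups, intake)
    assert res.loc["best", "dqi"] == 100
    assert res.loc["worst", "dqi"] == 0


def test_dqi_matches_exhaustive_hand_scoring(rng):
    rubric = load_dqi_rubric()
    n = 3
    idx = [f"s{i}" for i in range(n)]
    groups = pd.DataFrame(
        {c: rng.uniform(0, 4, n) for c in
         ["vegetables", "fruit_nuts", "cereals", "legumes", "fish_seafood",
          "dairy", "meat", "empty_calorie_foods"]},
        index=idx,
    )
    intake = pd.DataFrame(
        {
            "energy": rng.uniform(1500, 2500, n),
            "fiber": rng.uniform(0, 35, n), "protein": rng.uniform(20, 100, n),
            "iron": rng.uniform(0, 20, n), "calcium": rng.uniform(100, 1400, n),
            "vitamin_c": rng.uniform(0, 120, n),
            "total_fat": rng.uniform(30, 120, n),
            "saturated_fat": rng.uniform(5, 50, n),
            "mufa": rng.uniform(5, 40, n), "pufa": rng.uniform(2, 25, n),
            "cholesterol": rng.uniform(50, 600, n),
            "sodium": rng.uniform(1000, 5000, n),
            "carbohydrate": rng.uniform(100, 400, n),
        },
        index=idx,
    )
    res = compute_dqi(groups, intake)
    energy = intake["energy"]
    derived = {
        "food_group_variety": (groups[["vegetables", "fruit_nuts", "cereals",
                                       "dairy", "meat", "fish_seafood",
                                       "legumes"]] > 0).sum(axis=1),
        "protein_source_variety": (groups[["meat", "fish_seafood", "legumes",
                                           "dairy"]] > 0).sum(axis=1),
        "total_fat_pct": intake["total_fat"] * 9 / energy * 100,
        "saturated_fat_pct": intake["saturated_fat"] * 9 / energy * 100,
        "carb_pct_dev": (intake["carbohydrate"] * 4 / energy * 100 - 57.5).abs(),
        "fat_ratio_dev": ((intake["mufa"] + intake["pufa"]) / intake["saturated_fat"] - 1.75).abs(),
    }
    for subj in idx:
        total = 0
        for comp, row in rubric.iterrows():
            src = row["source"]
            if src.startswith("derived:"):
                v = derived[src.split(":", 1)[1]][subj]
            elif src in groups.columns:
                v = groups.loc[subj, src]
            else:
                v = intake.loc[subj, src]
            if row["direction"] == "higher_better":
                total += sum(v >= t for t in row["thresholds"])
            else:
                total += sum(v <= t for t in row["thresholds"])
        assert res.loc[subj, "dqi"] == total


# -------------------------------------------------------- standardize ----


def test_standardize_scores_properties():
    z = standardize_scores(pd.Series([1.0, 2.0, 3.0]))
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=0) == pytest.approx(1.0)
    pd.testing.assert_series_equal(standardize_scores(z), z)
    with pytest.raises(ValueError, match="zero-variance"):
        standardize_scores(pd.Series([2.0, 2.0, 2.0]))
    with pytest.raises(ValueError, match="n >= 2"):
        standardize_scores(pd.Series([1.0]))
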