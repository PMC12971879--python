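"""Dietary index scoring: DII, MMDS, HEI-2015 and DQI.

All scoring standards live in editable config tables packaged under
``diet2gut/data``:

* ``dii_effect_scores.csv`` — 35 dietary parameters with literature-style
  inflammatory effect scores plus global reference means/SDs;
* ``hei2015_standards.csv`` — the 13 HEI-2015 components with density bases
  and min/max standards (maxima sum to 100);
* ``mmds_config.yaml`` — Mediterranean-score component lists, the reverse
  coding and the recommended alcohol range (maximum total 10);
* ``dqi_rubric.csv`` — a 100-point variety/adequacy/moderation/balance rubric
  on 0-3 / 0-5 / 0-6 point scales.

The scorers all operate on an intake table (subjects x dietary parameters in
physical units, energy in kcal/day) and a food-group table (subjects x
servings/day), subject ids aligned on the index.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "load_dii_effects",
    "load_hei_standards",
    "load_mmds_config",
    "load_dqi_rubric",
    "compute_dii",
    "compute_mmds",
    "compute_hei",
    "compute_dqi",
    "standardize_scores",
    "score_all",
]


def _data_file(name: str):
    return resources.files("diet2gut.data").joinpath(name)


def load_dii_effects() -> pd.DataFrame:
    """Load the packaged 35-parameter inflammatory effect-score table."""
    with _data_file("dii_effect_scores.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", index_col="parameter")
    if len(df) != 35:
        raise ValueError(f"effect-score table must have 35 parameters, found {len(df)}")
    if not np.isfinite(df["effect_score"]).all():
        raise ValueError("effect scores must be finite")
    return df


def load_hei_standards() -> pd.DataFrame:
    """Load the packaged HEI-2015 standards (13 components summing to 100)."""
    with _data_file("hei2015_standards.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", index_col="component")
    _validate_hei_standards(df)
    return df


def _validate_hei_standards(df: pd.DataFrame) -> None:
    if len(df) != 13:
        raise ValueError(f"HEI standards must have exactly 13 components, found {len(df)}")
    total = df["max_points"].sum()
    if total != 100:
        raise ValueError(f"HEI component maxima must sum to 100, found {total}")
    bad = df[~df["type"].isin(["adequacy", "moderation"])]
    if len(bad):
        raise ValueError(f"unknown HEI component type(s): {list(bad.index)}")


def load_mmds_config() -> dict:
    """Load the packaged Mediterranean-diet-score configuration."""
    with _data_file("mmds_config.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    for key in ("beneficial", "reverse_coded", "alcohol_range", "fat_ratio"):
        if key not in cfg:
            raise ValueError(f"MMDS config missing key {key!r}")
    lo, hi = cfg["alcohol_range"]
    if not lo <= hi:
        raise ValueError("alcohol_range must be [low, high] with low <= high")
    return cfg


def load_dqi_rubric() -> pd.DataFrame:
    """Load the packaged diet-quality-index rubric (maxima sum to <= 100)."""
    with _data_file("dqi_rubric.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", index_col="component")
    df["thresholds"] = df["thresholds"].map(
        lambda s: [float(t) for t in str(s).split(";")]
    )
    for comp, row in df.iterrows():
        if len(row["thresholds"]) != row["max_points"]:
            raise ValueError(f"DQI component {comp!r}: thresholds must match max_points")
    if df["max_points"].sum() > 100:
        raise ValueError("DQI maximum attainable total must be <= 100")
    return df


def compute_dii(
    intake: pd.DataFrame,
    effects: pd.DataFrame | None = None,
    mode: str = "cohort",
) -> pd.DataFrame:
    """Dietary inflammatory index per subject.

    Each parameter's intake is z-scored (cohort mean/SD with population SD in
    ``"cohort"`` mode, packaged reference mean/SD in ``"global"`` mode),
    converted to a standard-normal percentile, centered to [-1, 1] via
    ``2*Phi(z) - 1``, and multiplied by the parameter's inflammatory effect
    score; the DII is the sum over parameters. Returns a frame with the
    ``dii`` total followed by per-parameter contributions.
    """
    if effects is None:
        effects = load_dii_effects()
    if mode not in ("cohort", "global"):
        raise ValueError(f"mode must be 'cohort' or 'global', got {mode!r}")
    missing = [p for p in effects.index if p not in intake.columns]
    if missing:
        raise ValueError(f"intake table missing DII parameter(s): {missing}")
    x = intake[list(effects.index)].astype(float)
    if (x < 0).any().any():
        bad = x.columns[(x < 0).any()].tolist()
        raise ValueError(f"negative intake values in parameter(s): {bad}")
    if mode == "cohort":
        if len(x) < 2:
            raise ValueError("cohort mode requires at least 2 subjects")
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        zero_sd = sd.index[sd == 0].tolist()
        if zero_sd:
            raise ValueError(f"zero-SD parameter(s) in cohort mode: {zero_sd}")
    else:
        mu = effects["ref_mean"]
        sd = effects["ref_sd"]
    z = (x - mu) / sd
    centered = 2.0 * norm.cdf(z) - 1.0
    contrib = pd.DataFrame(
        centered * effects["effect_score"].to_numpy(), index=x.index, columns=x.columns
    )
    out = pd.DataFrame({"dii": contrib.sum(axis=1)})
    return pd.concat([out, contrib], axis=1)


def _fat_ratio(intake: pd.DataFrame, cfg: dict) -> pd.Series:
    num = intake[cfg["fat_ratio"]["numerator"]].sum(axis=1)
    den = intake[cfg["fat_ratio"]["denominator"]]
    zero = den.index[den == 0].tolist()
    if zero:
        raise ValueError(
            f"fat ratio undefined (saturated fat = 0) for subject(s): {zero}"
        )
    return num / den


def compute_mmds(
    groups: pd.DataFrame,
    intake: pd.DataFrame,
    cfg: dict | None = None,
) -> pd.DataFrame:
    """Modified Mediterranean diet score per subject (integer total).

    Beneficial components (including the MUFA+PUFA/SFA fat ratio) score 1
    strictly above the cohort median, reverse-coded components 1 strictly
    below it (ties score 0 in both directions), and alcohol scores 1 inside
    the recommended range (inclusive).
    """
    if cfg is None:
        cfg = load_mmds_config()
    if len(groups) < 2:
        raise ValueError("MMDS requires at least 2 subjects (cohort medians)")

    values: dict[str, pd.Series] = {}
    for comp in cfg["beneficial"]:
        if comp == "fat_ratio":
            values[comp] = _fat_ratio(intake, cfg)
        elif comp in groups.columns:
            values[comp] = groups[comp].astype(float)
        elif comp in intake.columns:
            values[comp] = intake[comp].astype(float)
        else:
            raise ValueError(f"MMDS component column missing: {comp!r}")
    for comp in cfg["reverse_coded"]:
        if comp in groups.columns:
            values[comp] = groups[comp].astype(float)
        elif comp in intake.columns:
            values[comp] = intake[comp].astype(float)
        else:
            raise ValueError(f"MMDS component column missing: {comp!r}")

    points = {}
    for comp in cfg["beneficial"]:
        v = values[comp]
        points[comp] = (v > v.median()).astype(int)
    for comp in cfg["reverse_coded"]:
        v = values[comp]
        points[comp] = (v < v.median()).astype(int)
    if "alcohol" not in intake.columns:
        raise ValueError("MMDS component column missing: 'alcohol'")
    lo, hi = cfg["alcohol_range"]
    points["alcohol"] = ((intake["alcohol"] >= lo) & (intake["alcohol"] <= hi)).astype(int)

    comp_df = pd.DataFrame(points, index=groups.index)
    out = pd.DataFrame({"mmds": comp_df.sum(axis=1).astype(int)})
    return pd.concat([out, comp_df], axis=1)


def mmds_max(cfg: dict | None = None) -> int:
    """Configured maximum attainable MMDS total."""
    if cfg is None:
        cfg = load_mmds_config()
    return len(cfg["beneficial"]) + len(cfg["reverse_coded"]) + 1


def _hei_densities(
    groups: pd.DataFrame, intake: pd.DataFrame, standards: pd.DataFrame
) -> pd.DataFrame:
    energy = intake["energy"].astype(float)
    if (energy <= 0).any():
        bad = energy.index[energy <= 0].tolist()
        raise ValueError(f"non-positive energy for subject(s): {bad}")
    sfa = intake["saturated_fat"].astype(float)
    derived = {
        "fatty_acid_ratio": np.where(
            sfa > 0, (intake["mufa"] + intake["pufa"]) / sfa.replace(0, np.nan), np.inf
        ),
        "added_sugars_pct": intake["added_sugars"] * 4.0 / energy * 100.0,
        "saturated_fat_pct": sfa * 9.0 / energy * 100.0,
        "sodium_g": intake["sodium"] / 1000.0,
    }
    dens = {}
    for comp, row in standards.iterrows():
        src = row["source"]
        if src in derived:
            value = pd.Series(derived[src], index=intake.index)
        elif src in groups.columns:
            value = groups[src].astype(float)
        elif src in intake.columns:
            value = intake[src].astype(float)
        else:
            raise ValueError(f"HEI source column missing: {src!r} (component {comp!r})")
        if row["basis"] == "per_1000kcal":
            value = value / energy * 1000.0
        dens[comp] = value
    return pd.DataFrame(dens, index=intake.index)


def compute_hei(
    groups: pd.DataFrame,
    intake: pd.DataFrame,
    standards: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """HEI-2015 total and 13 component scores per subject.

    Component densities are amounts per 1,000 kcal (or a ratio / % of energy
    as declared). Adequacy components scale linearly from 0 at the minimum
    standard to full points at/above the maximum standard; moderation
    components earn full points at/below their maximum standard and 0 at/above
    their minimum standard, linear in between. The total is the component sum
    and lies in [0, 100].
    """
    if standards is None:
        standards = load_hei_standards()
    else:
        _validate_hei_standards(standards)
    dens = _hei_densities(groups, intake, standards)
    scores = {}
    for comp, row in standards.iterrows():
        d = dens[comp]
        pts, hi, lo = row["max_points"], row["std_max"], row["std_min"]
        if row["type"] == "adequacy":
            frac = (d - lo) / (hi - lo)
        else:  # moderation: hi (std_max) < lo (std_min), full points at low density
            frac = (lo - d) / (lo - hi)
        scores[comp] = pts * np.clip(frac, 0.0, 1.0)
    comp_df = pd.DataFrame(scores, index=intake.index)
    out = pd.DataFrame({"hei": comp_df.sum(axis=1)})
    return pd.concat([out, comp_df], axis=1)


_DQI_MAJOR_GROUPS = [
    "vegetables", "fruit_nuts", "cereals", "dairy", "meat", "fish_seafood", "legumes",
]
_DQI_PROTEIN_SOURCES = ["meat", "fish_seafood", "legumes", "dairy"]


def _dqi_derived(groups: pd.DataFrame, intake: pd.DataFrame) -> dict[str, pd.Series]:
    energy = intake["energy"].astype(float)
    if (energy <= 0).any():
        bad = energy.index[energy <= 0].tolist()
        raise ValueError(f"non-positive energy for subject(s): {bad}")
    sfa = intake["saturated_fat"].astype(float)
    ratio = pd.Series(
        np.where(sfa > 0, (intake["mufa"] + intake["pufa"]) / sfa.replace(0, np.nan), np.inf),
        index=intake.index,
    )
    present = [g for g in _DQI_MAJOR_GROUPS if g in groups.columns]
    protein = [g for g in _DQI_PROTEIN_SOURCES if g in groups.columns]
    return {
        "food_group_variety": (groups[present] > 0).sum(axis=1).astype(float),
        "protein_source_variety": (groups[protein] > 0).sum(axis=1).astype(float),
        "total_fat_pct": intake["total_fat"] * 9.0 / energy * 100.0,
        "saturated_fat_pct": sfa * 9.0 / energy * 100.0,
        "carb_pct_dev": (intake["carbohydrate"] * 4.0 / energy * 100.0 - 57.5).abs(),
        "fat_ratio_dev": (ratio - 1.75).abs(),
    }


def compute_dqi(
    groups: pd.DataFrame,
    intake: pd.DataFrame,
    rubric: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Diet quality index total and component scores per subject.

    Each rubric component maps its source value onto a 0-3 / 0-5 / 0-6 point
    scale: one point per threshold reached (at-or-above for ``higher_better``
    components, at-or-below for ``lower_better``). The total lies in [0, 100].
    """
    if rubric is None:
        rubric = load_dqi_rubric()
    derived = _dqi_derived(groups, intake)
    scores = {}
    for comp, row in rubric.iterrows():
        src = row["source"]
        if src.startswith("derived:"):
            key = src.split(":", 1)[1]
            if key not in derived:
                raise ValueError(f"unknown derived DQI source {key!r}")
            value = derived[key]
        elif src in groups.columns:
            value = groups[src].astype(float)
        elif src in intake.columns:
            value = intake[src].astype(float)
        else:
            raise ValueError(f"DQI source column missing: {src!r} (component {comp!r})")
        thresholds = row["thresholds"]
        if row["direction"] == "higher_better":
            pts = sum((value >= t).astype(int) for t in thresholds)
        elif row["direction"] == "lower_better":
            pts = sum((value <= t).astype(int) for t in thresholds)
        else:
            raise ValueError(f"unknown DQI direction {row['direction']!r}")
        scores[comp] = pts
    comp_df = pd.DataFrame(scores, index=groups.index)
    out = pd.DataFrame({"dqi": comp_df.sum(axis=1).astype(int)})
    return pd.concat([out, comp_df], axis=1)


def standardize_scores(values: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Z-score a vector (or each column) to mean 0, SD 1 (population SD)."""
    if len(values) < 2:
        raise ValueError("standardization requires n >= 2")
    mu = values.mean(axis=0) if isinstance(values, pd.DataFrame) else values.mean()
    sd = values.std(axis=0, ddof=0) if isinstance(values, pd.DataFrame) else values.std(ddof=0)
    if np.any(np.asarray(sd) == 0):
        raise ValueError("cannot standardize a zero-variance vector")
    return (values - mu) / sd


def score_all(
    intake: pd.DataFrame,
    groups: pd.DataFrame,
    dii_mode: str = "cohort",
) -> pd.DataFrame:
    """Compute all four index totals plus z-scored versions per subject."""
    totals = pd.DataFrame(
        {
            "dii": compute_dii(intake, mode=dii_mode)["dii"],
            "mmds": compute_mmds(groups, intake)["mmds"],
            "hei": compute_hei(groups, intake)["hei"],
            "dqi": compute_dqi(groups, intake)["dqi"],
        }
    )
    z = standardize_scores(totals)
    z.columns = [f"{c}_z" for c in totals.columns]
    return pd.concat([totals, z], axis=1)
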