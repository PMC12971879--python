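"""Synthetic mother-infant cohort generator with a planted mediation chain.

The generator emulates the statistical structure that the downstream analysis
assumes, so the whole pipeline is testable without any sequencing download:

* a standard-normal per-dyad diet driver ``X`` (interpreted as a healthy-diet
  propensity) plus a correlated inflammatory driver, so that healthy and
  inflammatory dietary indices computed from the synthetic intakes are
  negatively correlated;
* dyad metadata with a configurable caesarean fraction (default 26%, matching
  the emulated cohort of 104 dyads);
* maternal and infant genus-level count tables drawn from a logistic-normal
  composition via per-sample multinomials at lognormally varying depths, with
  Bernoulli zero-masking concentrated on rare genera;
* a planted causal chain on the centered-log-ratio (CLR) scale:
  mediator ``M* = alpha1 + a*X + beta2*C + e1`` (a maternal genus) and outcome
  ``Y* = alpha2 + c'*X + b*M* + beta4*C + e2`` (an infant genus), where ``C``
  is delivery mode. The planted genera are abundant "core" taxa and the chain
  is injected so that the CLR value computed by the analysis pipeline over the
  core genus set equals the latent value up to multinomial count noise; fitted
  path coefficients are therefore directly comparable to the planted truth.

Genus composition uses a two-tier design: a "common" tier of abundant genera
(which the core filter retains) and a "rare" tier of very low-abundance genera
(which it drops), making the realized core set stable across seeds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .indices import load_dii_effects

__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "generate_cohort",
    "generate_intakes",
    "generate_taxa_counts",
    "INTAKE_UNITS",
]

# Realistic adult/infant gut genus names for the common (abundant) tier; filler
# names are appended if more genera are requested than the lists provide.
_MATERNAL_COMMON = [
    "Bacteroides", "Faecalibacterium", "Blautia", "Bifidobacterium",
    "Coprococcus", "Roseburia", "Prevotella", "Ruminococcus", "Anaerostipes",
    "Romboutsia", "Dorea", "Fusicatenibacter", "Agathobacter",
    "Subdoligranulum", "Alistipes", "Akkermansia", "Lachnospira",
    "Butyricicoccus", "Monoglobus", "Christensenellaceae_R7",
    "Eubacterium_coprostanoligenes", "Oscillibacter", "Parabacteroides",
    "Phascolarctobacterium", "Streptococcus", "Collinsella", "Holdemanella",
    "Lachnoclostridium", "Dialister", "Veillonella",
]
_INFANT_COMMON = [
    "Bifidobacterium", "Bacteroides", "Veillonella", "Escherichia_Shigella",
    "Streptococcus", "Klebsiella", "Enterococcus", "Clostridium_sensu_stricto",
    "Lactobacillus", "Staphylococcus", "Parabacteroides", "Haemophilus",
    "Rothia", "Collinsella", "Blautia", "Akkermansia", "Citrobacter",
    "Enterobacter", "Lacticaseibacillus", "Cutibacterium",
]

# Intake columns beyond the 35 inflammatory-index parameters, needed by the
# HEI/DQI/MMDS scorers: (baseline, driver) where driver is "healthy",
# "inflammatory" or None.
_EXTRA_INTAKE = {
    "sodium": (2400.0, "inflammatory"),   # mg/day
    "calcium": (900.0, "healthy"),        # mg/day
    "added_sugars": (40.0, "inflammatory"),  # g/day
}

_FOOD_GROUPS = {
    # group: (baseline servings/day, driver)
    "vegetables": (2.0, "healthy"),
    "legumes": (0.3, "healthy"),
    "fruit_nuts": (2.0, "healthy"),
    "fish_seafood": (0.5, "healthy"),
    "cereals": (4.0, "healthy"),
    "meat": (1.0, "inflammatory"),
    "meat_products": (0.5, "inflammatory"),
    "dairy": (2.0, "inflammatory"),
    "total_fruits": (1.5, "healthy"),
    "whole_fruits": (1.0, "healthy"),
    "total_vegetables": (2.0, "healthy"),
    "greens_beans": (0.4, "healthy"),
    "whole_grains": (1.5, "healthy"),
    "total_protein": (2.0, None),
    "seafood_plant_protein": (0.8, "healthy"),
    "refined_grains": (3.0, "inflammatory"),
    "empty_calorie_foods": (1.0, "inflammatory"),
}

INTAKE_UNITS = {
    "sodium": "mg/day",
    "calcium": "mg/day",
    "added_sugars": "g/day",
    # the 35 index parameters carry their units in the packaged effect table
}


@dataclass
class CohortConfig:
    """Configuration of the synthetic mother-infant cohort.

    Defaults mirror the emulated cohort (104 dyads, 26% caesarean) and the
    headline planted mediation chain (a=-0.66, b=-0.23, c'=-0.67 on the CLR /
    standardized-exposure scale). Depth and zero-inflation defaults are
    conventions, not measured properties of any real dataset.
    """

    n_dyads: int = 104
    caesarean_prob: float = 0.26
    n_maternal_genera: int = 40
    n_infant_genera: int = 25
    seq_depth_mean: int = 10_000
    zero_inflation: float = 0.05
    a_true: float = -0.66
    b_true: float = -0.23
    c_prime_true: float = -0.67
    beta2_true: float = 0.30
    beta4_true: float = -0.40
    mediator_noise_sd: float = 1.0
    outcome_noise_sd: float = 1.0
    diet_corr_target: float = -0.61
    intake_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 3:
            raise ValueError("n_dyads must be >= 3")
        for name in ("caesarean_prob", "zero_inflation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_maternal_genera < 2 or self.n_infant_genera < 2:
            raise ValueError("genus counts must be >= 2")
        if self.seq_depth_mean < 100:
            raise ValueError("seq_depth_mean must be >= 100")
        if not -1.0 < self.diet_corr_target < 0.0:
            raise ValueError("diet_corr_target must lie in (-1, 0)")
        if self.seed is None:
            raise ValueError("a seed is required for reproducible generation")


@dataclass
class PlantedTruth:
    """Ground-truth path coefficients and planted genus identities."""

    a_true: float
    b_true: float
    c_prime_true: float
    beta2_true: float
    beta4_true: float
    mediator_genus: str
    outcome_genus: str

    def to_dict(self) -> dict:
        return asdict(self)


def _genus_names(common_pool: Sequence[str], n_common: int, n_rare: int,
                 prefix: str) -> tuple[list[str], list[str]]:
    common = list(common_pool[:n_common])
    for i in range(len(common), n_common):
        common.append(f"{prefix}_common_{i:03d}")
    rare = [f"{prefix}_rare_{i:03d}" for i in range(n_rare)]
    return common, rare


def _split_tiers(n_genera: int) -> tuple[int, int]:
    # 75% of genera abundant (core tier), 25% rare
    n_common = max(2, int(np.ceil(0.75 * n_genera)))
    return n_common, n_genera - n_common


def generate_taxa_counts(
    latent_log_abundances: pd.DataFrame,
    depths: np.ndarray,
    zero_inflation: float | np.ndarray,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw a genus count table from latent per-sample log-abundances.

    Each sample's composition is the softmax of its latent row; counts are a
    multinomial draw at the sample's depth, after which entries are masked to
    zero by independent Bernoulli trials. ``zero_inflation`` may be a scalar
    (uniform masking rate) or a per-genus vector of rates. Row sums equal the
    drawn depths before masking.
    """
    z = np.asarray(latent_log_abundances, dtype=float)
    if np.isnan(z).any():
        raise ValueError("latent log-abundances contain NaN")
    depths = np.asarray(depths)
    if (depths < 1).any():
        raise ValueError("all sequencing depths must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # softmax per row, tolerating -inf latents (zero probability)
    zmax = np.max(z, axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)

    counts = np.vstack([
        rng.multinomial(int(depths[i]), probs[i]) for i in range(z.shape[0])
    ])

    rate = np.broadcast_to(np.asarray(zero_inflation, dtype=float), (z.shape[1],))
    if (rate < 0).any() or (rate > 1).any():
        raise ValueError("zero_inflation rates must lie in [0, 1]")
    if (rate > 0).any():
        mask = rng.random(counts.shape) < rate[None, :]
        counts = np.where(mask, 0, counts)

    return pd.DataFrame(
        counts,
        index=latent_log_abundances.index,
        columns=latent_log_abundances.columns,
    )


def generate_intakes(
    config: CohortConfig,
    diet_driver: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate intake and food-group tables from the healthy-diet driver.

    Intakes are lognormal around parameter-specific baselines (the packaged
    reference means for the 35 inflammatory-index parameters). Healthy
    parameters and food groups load positively on the driver; pro-inflammatory
    ones load positively on a correlated inflammatory driver (correlation
    ``config.diet_corr_target`` with the healthy driver), i.e. negatively on
    the healthy driver. With ``intake_noise_sd == 0`` the generator is fully
    deterministic given the driver: an all-zero driver returns every subject's
    baseline profile exactly.
    """
    x = np.asarray(diet_driver, dtype=float)
    if x.shape[0] != config.n_dyads:
        raise ValueError("diet_driver length must equal n_dyads")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[1])

    t = config.diet_corr_target
    noise_on = config.intake_noise_sd > 0
    # inflammatory driver: correlation t with the healthy driver; its
    # idiosyncratic part counts as generator noise (off in deterministic mode)
    xi = rng.standard_normal(config.n_dyads) if noise_on else np.zeros_like(x)
    x_inf = t * x + np.sqrt(1.0 - t * t) * xi

    effects = load_dii_effects()
    lam = 0.4
    cols: dict[str, np.ndarray] = {}
    for row in effects.itertuples():
        baseline = row.ref_mean
        drv = x_inf if row.effect_score > 0 else x
        eta = rng.standard_normal(config.n_dyads) * config.intake_noise_sd
        cols[row.Index] = baseline * np.exp(lam * drv + eta)
    for name, (baseline, driver) in _EXTRA_INTAKE.items():
        drv = x_inf if driver == "inflammatory" else x
        eta = rng.standard_normal(config.n_dyads) * config.intake_noise_sd
        cols[name] = baseline * np.exp(lam * drv + eta)

    idx = pd.Index([f"dyad_{i:03d}" for i in range(config.n_dyads)], name="dyad_id")
    intake = pd.DataFrame(cols, index=idx)

    gcols: dict[str, np.ndarray] = {}
    for name, (baseline, driver) in _FOOD_GROUPS.items():
        if driver == "healthy":
            drv = 0.5 * x
        elif driver == "inflammatory":
            drv = 0.5 * x_inf
        else:
            drv = np.zeros_like(x)
        eta = rng.standard_normal(config.n_dyads) * config.intake_noise_sd
        gcols[name] = baseline * np.exp(drv + eta)
    groups = pd.DataFrame(gcols, index=idx)
    return intake, groups


def _latent_table(
    rng: np.random.Generator,
    n: int,
    common: list[str],
    rare: list[str],
    planted_genus: str,
    planted_values: np.ndarray,
) -> pd.DataFrame:
    """Latent log-abundances with one genus pinned to a target CLR value.

    The planted genus's latent is solved so that its CLR over the common
    (intended-core) genus set equals ``planted_values`` exactly.
    """
    k_c = len(common)
    mu_common = rng.normal(0.0, 1.2, size=k_c)
    med_idx = common.index(planted_genus)
    mu_common[med_idx] = 1.5  # keep the planted genus solidly abundant

    z = np.empty((n, k_c + len(rare)))
    for j in range(k_c):
        if j == med_idx:
            continue
        z[:, j] = mu_common[j] + 0.8 * rng.standard_normal(n)

    other = np.delete(np.arange(k_c), med_idx)
    s_other = z[:, other].sum(axis=1)
    # target CLR value is relative to the common-set mean; alpha anchors the
    # planted genus near its baseline abundance
    alpha = mu_common[med_idx] - mu_common.mean()
    target = planted_values + alpha
    z[:, med_idx] = (k_c * target + s_other) / (k_c - 1)

    for j, name in enumerate(rare):
        z[:, k_c + j] = rng.normal(-7.0, 0.7) + 0.8 * rng.standard_normal(n)

    idx = pd.Index([f"dyad_{i:03d}" for i in range(n)], name="dyad_id")
    return pd.DataFrame(z, index=idx, columns=common + rare)


def _masking_rates(latents: pd.DataFrame, mean_rate: float) -> np.ndarray:
    """Per-genus Bernoulli masking rates, concentrated on rare genera.

    Structural zeros in genus tables overwhelmingly hit rare taxa; weighting
    by inverse abundance keeps the average masking rate at ``mean_rate``
    without planting implausible hard zeros in dominant genera.
    """
    if mean_rate == 0:
        return np.zeros(latents.shape[1])
    z = np.asarray(latents, dtype=float)
    mean_rel = np.exp(z - z.max(axis=1, keepdims=True))
    mean_rel = (mean_rel / mean_rel.sum(axis=1, keepdims=True)).mean(axis=0)
    u = 1.0 / (1.0 + (mean_rel / 1e-4) ** 2)
    return np.clip(mean_rate * u / u.mean(), 0.0, 1.0)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate a full synthetic cohort.

    Returns ``(metadata, intake, food_groups, maternal_counts, infant_counts,
    truth)``. Metadata includes the latent standard-normal diet driver
    (column ``diet_driver``) so that recovery analyses can use the exposure on
    the same scale the chain was planted on. Identical configs (including the
    seed) produce bit-identical outputs.
    """
    ss = np.random.SeedSequence(config.seed).spawn(8)
    rng_meta = np.random.default_rng(ss[0])
    rng_intake = np.random.default_rng(ss[1])
    rng_mat = np.random.default_rng(ss[2])
    rng_inf = np.random.default_rng(ss[3])
    rng_depth = np.random.default_rng(ss[4])
    rng_counts_m = np.random.default_rng(ss[5])
    rng_counts_i = np.random.default_rng(ss[6])

    n = config.n_dyads
    idx = pd.Index([f"dyad_{i:03d}" for i in range(n)], name="dyad_id")

    x = rng_meta.standard_normal(n)
    caesarean = rng_meta.random(n) < config.caesarean_prob
    c = caesarean.astype(float)
    metadata = pd.DataFrame(
        {
            "delivery_mode": np.where(caesarean, "caesarean", "vaginal"),
            "infant_sex": np.where(rng_meta.random(n) < 0.5, "female", "male"),
            "antibiotics_pregnancy": (rng_meta.random(n) < 0.28).astype(int),
            "antibiotics_labor": (rng_meta.random(n) < 0.28).astype(int),
            "antibiotics_postpartum": (rng_meta.random(n) < 0.06).astype(int),
            "diet_driver": x,
        },
        index=idx,
    )

    intake, groups = generate_intakes(config, x, rng=rng_intake)

    nc_m, nr_m = _split_tiers(config.n_maternal_genera)
    nc_i, nr_i = _split_tiers(config.n_infant_genera)
    mat_common, mat_rare = _genus_names(_MATERNAL_COMMON, nc_m, nr_m, "m")
    inf_common, inf_rare = _genus_names(_INFANT_COMMON, nc_i, nr_i, "i")
    mediator_genus = "Coprococcus" if "Coprococcus" in mat_common else mat_common[0]
    outcome_genus = "Veillonella" if "Veillonella" in inf_common else inf_common[0]

    m_star = (
        config.a_true * x
        + config.beta2_true * c
        + config.mediator_noise_sd * rng_mat.standard_normal(n)
    )
    y_star = (
        config.c_prime_true * x
        + config.b_true * m_star
        + config.beta4_true * c
        + config.outcome_noise_sd * rng_inf.standard_normal(n)
    )

    z_mat = _latent_table(rng_mat, n, mat_common, mat_rare, mediator_genus, m_star)
    z_inf = _latent_table(rng_inf, n, inf_common, inf_rare, outcome_genus, y_star)

    sigma = 0.3
    depths_m = np.maximum(
        100,
        np.round(np.exp(rng_depth.normal(np.log(config.seq_depth_mean) - sigma**2 / 2, sigma, n))),
    ).astype(int)
    depths_i = np.maximum(
        100,
        np.round(np.exp(rng_depth.normal(np.log(config.seq_depth_mean) - sigma**2 / 2, sigma, n))),
    ).astype(int)

    maternal = generate_taxa_counts(
        z_mat, depths_m, _masking_rates(z_mat, config.zero_inflation), rng_counts_m
    )
    infant = generate_taxa_counts(
        z_inf, depths_i, _masking_rates(z_inf, config.zero_inflation), rng_counts_i
    )

    truth = PlantedTruth(
        a_true=config.a_true,
        b_true=config.b_true,
        c_prime_true=config.c_prime_true,
        beta2_true=config.beta2_true,
        beta4_true=config.beta4_true,
        mediator_genus=mediator_genus,
        outcome_genus=outcome_genus,
    )
    return metadata, intake, groups, maternal, infant, truth
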