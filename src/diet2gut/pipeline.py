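"""End-to-end pipeline: synthesize-or-load -> scores -> prep -> screen ->
mediation -> patterns, with provenance-stamped artifacts and a JSON report.

Every stage writes its artifact tables (tab-separated, ``#`` provenance
headers) into the output directory; the final report collects a cohort
summary (median [Q1-Q3] and count/percentage rows), the screening table
location, mediation summaries and the dietary-pattern summary, plus a
provenance block (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indices import score_all, standardize_scores
from .io import read_table, write_table
from .mediation import run_cma_suite
from .microbiome import CoreDefinition, alpha_diversity, clr_transform, core_taxa, to_relative
from .patterns import kmeans_fit, kmeans_scan, pca_decompose, select_k_elbow, top_correlated_items
from .screen import screen_associations
from .synthetic import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "summarize_cohort"]

log = logging.getLogger("diet2gut")

_KNOWN_KEYS = {
    "seed", "out_dir", "synth", "inputs", "core", "pseudocount", "dii_mode",
    "screen", "mediation", "patterns", "log_level",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    out_dir: str = "diet2gut_out"
    synth: dict | None = None            # CohortConfig overrides; None => load inputs
    inputs: dict | None = None           # paths: metadata, intake, groups, maternal_counts, infant_counts
    core: dict = dc_field(default_factory=lambda: {"prevalence": 0.5, "detection": 1e-5})
    pseudocount: float = 1e-6
    dii_mode: str = "cohort"
    screen: dict = dc_field(default_factory=lambda: {"family": "joint"})
    mediation: dict = dc_field(
        default_factory=lambda: {"exposures": ["dii_z"], "outcomes": "auto", "n_boot": 1000, "top_k": 8}
    )
    patterns: dict = dc_field(default_factory=lambda: {"k": 3, "k_max": 10})
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        # hash the analysis-relevant settings only, so reruns into a
        # different directory produce byte-identical artifacts
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("out_dir", "log_level")}
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def summarize_cohort(metadata: pd.DataFrame, scores: pd.DataFrame) -> dict:
    """Cohort summary: median [Q1-Q3] for continuous fields, counts and
    percentages (2 decimals) for categoricals.

    Quartiles use linear interpolation between order statistics.
    """
    if len(metadata) == 0:
        raise ValueError("empty metadata")
    n = len(metadata)
    out: dict[str, dict] = {"n_dyads": n, "continuous": {}, "categorical": {}}
    for col in ("dii", "mmds", "hei", "dqi"):
        if col in scores.columns:
            v = scores[col].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            out["continuous"][col] = {
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "display": f"{med:.2f} [{q1:.2f}-{q3:.2f}]",
            }
    for col in metadata.columns:
        if col == "diet_driver":
            continue
        series = metadata[col]
        if series.dtype == object or series.nunique() <= 4:
            levels = {}
            for level, count in series.value_counts().items():
                levels[str(level)] = {
                    "count": int(count),
                    "display": f"{count} ({count}/{n}, {100.0 * count / n:.2f}%)",
                }
            for level in sorted(set(series.unique()) - set(series.value_counts().index)):
                levels[str(level)] = {"count": 0, "display": f"0 (0/{n}, 0.00%)"}
            out["categorical"][col] = levels
    return out


def _load_inputs(cfg: PipelineConfig, stage: str):
    paths = cfg.inputs or {}
    need = {
        "scores": ["metadata", "intake", "groups"],
        "prep": ["maternal_counts", "infant_counts"],
    }[stage]
    missing = [k for k in need if k not in paths]
    if missing:
        raise ValueError(f"{stage} stage: missing input path(s) {missing}")
    for key in need:
        if not os.path.exists(paths[key]):
            raise FileNotFoundError(f"{stage} stage: input {key!r} not found at {paths[key]}")
    return [read_table(paths[k]) for k in need]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the report dictionary (also written
    to ``<out_dir>/report.json``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    prov = {"config_hash": config.digest(), "seed": config.seed, "version": __version__}
    truth = None

    # --- stage: cohort (synthesize or defer to loaders) -------------------
    if config.synth is not None:
        synth_cfg = CohortConfig(**{"seed": config.seed, **config.synth})
        metadata, intake, groups, mat_counts, inf_counts, truth = generate_cohort(synth_cfg)
        for name, df in [
            ("metadata", metadata), ("intake", intake), ("food_groups", groups),
            ("maternal_counts", mat_counts), ("infant_counts", inf_counts),
        ]:
            write_table(df, os.path.join(out, f"{name}.tsv"), provenance=prov)
        with open(os.path.join(out, "planted_truth.json"), "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2)
        # units sidecar for the intake table
        from .indices import load_dii_effects
        from .synthetic import INTAKE_UNITS
        units = dict(load_dii_effects()["unit"]) | INTAKE_UNITS
        with open(os.path.join(out, "intake.units.json"), "w") as fh:
            json.dump(units, fh, indent=2)
        log.info("synth: %d dyads, %d maternal x %d infant genera",
                 len(metadata), mat_counts.shape[1], inf_counts.shape[1])
    else:
        metadata, intake, groups = _load_inputs(config, "scores")
        mat_counts = inf_counts = None

    # --- stage: diet scores ------------------------------------------------
    scores = score_all(intake, groups, dii_mode=config.dii_mode)
    write_table(scores, os.path.join(out, "diet_scores.tsv"), provenance=prov)
    log.info("scores: %d subjects x %d columns", *scores.shape)

    # --- stage: microbiome prep -------------------------------------------
    if mat_counts is None:
        mat_counts, inf_counts = _load_inputs(config, "prep")
    core_def = CoreDefinition(
        prevalence_threshold=config.core.get("prevalence", 0.5),
        detection_threshold=config.core.get("detection", 1e-5),
    )
    clr, alpha, alpha_z = {}, {}, {}
    for label, counts in (("maternal", mat_counts), ("infant", inf_counts)):
        rel = to_relative(counts)
        core = core_taxa(rel, core_def)
        clr[label] = clr_transform(rel, core, pseudocount=config.pseudocount)
        alpha[label] = alpha_diversity(counts)
        alpha_z[label] = standardize_scores(alpha[label])
        write_table(clr[label], os.path.join(out, f"{label}_clr.tsv"), provenance=prov)
        write_table(alpha[label], os.path.join(out, f"{label}_alpha.tsv"), provenance=prov)
        log.info("prep[%s]: %d/%d genera core", label, len(core), counts.shape[1])

    # --- stage: association screen -----------------------------------------
    exposures = scores[[c for c in scores.columns if c.endswith("_z")]]
    outcomes = pd.concat(
        {
            "maternal": clr["maternal"], "infant": clr["infant"],
            "maternal_div": alpha_z["maternal"], "infant_div": alpha_z["infant"],
        },
        axis=1,
    )
    outcomes.columns = [f"{a}:{b}" for a, b in outcomes.columns]
    screen_table = screen_associations(
        exposures, outcomes, family=config.screen.get("family", "joint")
    )
    write_table(
        screen_table.set_index("exposure"),
        os.path.join(out, "screen.tsv"),
        provenance=prov,
    )
    log.info("screen: %d tests, %d raw-significant, %d FDR-significant",
             len(screen_table), int(screen_table["sig_raw"].sum()),
             int(screen_table["sig_fdr"].sum()))

    # --- stage: mediation ---------------------------------------------------
    med_cfg = dict(config.mediation)
    med_outcomes = med_cfg.get("outcomes", "auto")
    if med_outcomes == "auto":
        if truth is None:
            raise ValueError("mediation outcomes must be configured when loading real inputs")
        med_outcomes = [f"infant:{truth.outcome_genus}", "infant_div:Shannon"]
    delivery = (metadata["delivery_mode"] == "caesarean").astype(float)
    maternal_outcomes = pd.concat([clr["maternal"], alpha_z["maternal"]], axis=1)
    maternal_outcomes.columns = [
        f"maternal:{c}" if c in clr["maternal"].columns else f"maternal_div:{c}"
        for c in maternal_outcomes.columns
    ]
    med_tables = []
    for exposure_name in med_cfg.get("exposures", ["dii_z"]):
        for outcome_name in med_outcomes:
            if outcome_name not in outcomes.columns:
                raise ValueError(f"mediation outcome {outcome_name!r} not among screen outcomes")
            table, _ = run_cma_suite(
                exposures[exposure_name],
                exposure_name,
                maternal_outcomes,
                outcomes[outcome_name],
                outcome_name,
                delivery,
                screen_table,
                n_boot=med_cfg.get("n_boot", 1000),
                seed=config.seed,
            )
            med_tables.append(table)
            log.info("mediation[%s -> %s]: %d candidate mediators",
                     exposure_name, outcome_name, table.attrs["n_candidates"])
    mediation_table = (
        pd.concat(med_tables, ignore_index=True) if med_tables else pd.DataFrame()
    )
    if len(mediation_table):
        write_table(
            mediation_table.set_index("exposure"),
            os.path.join(out, "mediation.tsv"),
            provenance=prov,
        )

    # --- stage: dietary patterns -------------------------------------------
    pca = pca_decompose(scores[["dii", "mmds", "hei", "dqi"]], standardize=True)
    k_max = config.patterns.get("k_max", 10)
    wss = kmeans_scan(pca.scores, range(1, min(k_max, len(pca.scores)) + 1), seed=config.seed)
    k_elbow = select_k_elbow(wss)
    k_used = config.patterns.get("k", 3) or k_elbow
    clusters = kmeans_fit(pca.scores, k_used, seed=config.seed)
    write_table(pca.loadings, os.path.join(out, "pca_loadings.tsv"), provenance=prov)
    write_table(pca.scores, os.path.join(out, "pca_scores.tsv"), provenance=prov)
    write_table(clusters.labels.to_frame(), os.path.join(out, "clusters.tsv"), provenance=prov)
    top_items = top_correlated_items(scores[["dii", "mmds", "hei", "dqi"]], groups, k=8)
    write_table(top_items.set_index("index"), os.path.join(out, "top_items.tsv"), provenance=prov)
    log.info("patterns: elbow k=%d, used k=%d", k_elbow, k_used)

    # --- report -------------------------------------------------------------
    report = {
        "provenance": prov,
        "cohort_summary": summarize_cohort(metadata, scores),
        "screen": {
            "n_tests": len(screen_table),
            "n_raw_significant": int(screen_table["sig_raw"].sum()),
            "n_fdr_significant": int(screen_table["sig_fdr"].sum()),
            "note": (
                "raw-significant associations only; none survive FDR"
                if screen_table["sig_raw"].any() and not screen_table["sig_fdr"].any()
                else ""
            ),
        },
        "mediation": {
            "n_fits": len(mediation_table),
            "mean_c_prime_unadjusted": (
                float(mediation_table.loc[~mediation_table["adjusted"], "c_prime"].mean())
                if len(mediation_table)
                else None
            ),
        },
        "patterns": {
            "k_elbow": k_elbow,
            "k_used": k_used,
            "variance_explained": [float(v) for v in pca.variance_explained],
        },
    }
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report
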