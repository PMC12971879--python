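# diet2gut

Does the quality of a mother's diet during gestation shape her infant's gut
microbiota — and if so, how much of that influence travels *through* her own
gut microbes? `diet2gut` is a Python library for nutrition-microbiome
epidemiologists that implements the full analysis chain needed to ask that
question of a mother–infant cohort:

1. **Dietary index scoring** from FFQ-derived intake and food-group tables:
   the Dietary Inflammatory Index (DII), a modified Mediterranean diet score
   (MMDS, 0–10), the Healthy Eating Index (HEI-2015, 0–100) and a Diet
   Quality Index (DQI, 0–100), with every scoring standard in editable
   config tables.
2. **Compositional microbiome preprocessing**: relative abundances, an
   abundance-occurrence core filter (present in ≥ 50% of samples above
   0.001% relative abundance), centered log-ratio (CLR) transform, and
   alpha diversity (Observed, Chao1, Shannon, Simpson, InvSimpson, Fisher).
3. **Association screening**: one OLS per (index, outcome) pair with
   Benjamini–Hochberg FDR across the whole family.
4. **Causal mediation analysis**: for each candidate maternal-taxon mediator
   M, two regressions

       M = α₁ + a·X + β₂·C + ε₁
       Y = α₂ + c′·X + b·M + β₄·C + ε₂

   (X = standardized diet score, Y = infant outcome, C = delivery mode) give
   the indirect effect a·b and total effect c′ + a·b, with percentile CIs
   and two-tailed pseudo p-values from 1,000 dyad-level bootstrap resamples.
5. **Dietary patterns**: PCA over the indices plus k-means clustering with
   elbow-based k selection.
6. A **synthetic cohort generator** that emulates the whole data-generating
   process — correlated healthy/inflammatory diet drivers, zero-inflated
   overdispersed genus counts, and a mediation chain planted on the CLR
   scale — so the entire pipeline is testable without any sequencing data.

## Worked example

```python
from diet2gut import (CohortConfig, MediationSpec, bootstrap_mediation,
                      clr_transform, core_taxa, generate_cohort, to_relative)

cfg = CohortConfig(n_dyads=300, seed=42, a_true=-0.66, b_true=-0.23,
                   c_prime_true=-0.67)
meta, _, _, maternal, infant, truth = generate_cohort(cfg)

rel_m = to_relative(maternal); clr_m = clr_transform(rel_m, core_taxa(rel_m))
rel_i = to_relative(infant);   clr_i = clr_transform(rel_i, core_taxa(rel_i))

x = meta["diet_driver"]
c = (meta["delivery_mode"] == "caesarean").astype(float).to_frame("delivery_mode")
res = bootstrap_mediation(x, clr_m[truth.mediator_genus],
                          clr_i[truth.outcome_genus], covariates=c,
                          spec=MediationSpec(n_boot=1000, seed=0))
```

This run (`examples/05_mediation.py`) prints:

```
a  = -0.562 (truth -0.66)
b  = -0.263 (truth -0.23)
c' = -0.690 (truth -0.67)
indirect a*b = 0.148 (truth 0.1518)
total = c' + a*b = -0.542
95% bootstrap CI for a*b: [0.078, 0.222], pseudo p = 0.001
```

The generator planted a diet → *Coprococcus* → *Veillonella* chain with
paths a = −0.66 and b = −0.23 on the CLR scale; the fitted paths recover it
within sampling error, the indirect effect 0.148 matches the planted product
0.1518, and the bootstrap CI excludes zero — the mediation machinery detects
the planted pathway. Across 200 replicate cohorts the mean fitted indirect
effect agrees with 0.1518 to within Monte-Carlo error (see
`tests/test_acceptance.py`).

The other scripts in `examples/` walk through each capability one at a time:
cohort generation, index scoring, compositional prep, screening, patterns,
and the one-command end-to-end pipeline

```python
from diet2gut import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=7, out_dir="out", synth={"n_dyads": 104}))
```

which writes provenance-stamped TSV artifacts and a JSON report. A thin CLI
wraps the same functions: `diet2gut run --config config.yaml`, plus
`diet2gut synth|scores|prep` subcommands.

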