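"""Compositional microbiome preprocessing and alpha diversity.

Genus count tables (subjects x genera, nonnegative integers) are converted to
relative abundances, filtered to the core microbiota (taxa present above a
detection threshold in at least a prevalence fraction of samples), and
centered-log-ratio (CLR) transformed over the core genera. Alpha diversity is
computed on the raw counts via scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import alpha as skalpha

__all__ = [
    "CoreDefinition",
    "to_relative",
    "core_taxa",
    "clr_transform",
    "alpha_diversity",
]

ALPHA_METRICS = ["Observed", "Chao1", "Shannon", "Simpson", "InvSimpson", "Fisher"]


@dataclass
class CoreDefinition:
    """Core-microbiota definition: prevalence and detection thresholds.

    A genus is core when it exceeds ``detection_threshold`` relative abundance
    (strictly) in at least ``prevalence_threshold`` of the samples. Defaults
    implement the "present in at least 50% of samples above 0.001% relative
    abundance" convention.
    """

    prevalence_threshold: float = 0.50
    detection_threshold: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("prevalence_threshold", "detection_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a count table to relative abundances."""
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("count table contains negative entries")
    totals = arr.sum(axis=1)
    empty = counts.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"all-zero sample(s): {empty}")
    return counts.div(pd.Series(totals, index=counts.index), axis=0)


def core_taxa(rel: pd.DataFrame, core: CoreDefinition | None = None) -> list[str]:
    """Genera passing the core filter, in input column order."""
    if core is None:
        core = CoreDefinition()
    prevalence = (rel > core.detection_threshold).mean(axis=0)
    return [g for g in rel.columns if prevalence[g] >= core.prevalence_threshold]


def clr_transform(
    rel: pd.DataFrame,
    genera: list[str] | None = None,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Centered log-ratio transform over the given genera.

    Per sample, ``y_g = log(p_g + d) - mean_g log(p_g + d)`` where the mean
    runs over the included genera only (the core set when filtering precedes
    the transform) and ``d`` is the pseudocount added to the relative
    abundances. Rows sum to zero by construction.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    sub = rel if genera is None else rel[list(genera)]
    logp = np.log(sub.to_numpy(dtype=float) + pseudocount)
    clr = logp - logp.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=sub.index, columns=sub.columns)


def _alpha_row(counts: np.ndarray) -> list[float]:
    c = counts[counts > 0]
    shannon = skalpha.shannon(counts, base=np.e)
    simpson = skalpha.simpson(counts)
    inv_simpson = skalpha.inv_simpson(counts)
    if counts.sum() < 2:
        raise ValueError("Fisher's alpha needs at least 2 reads in a sample")
    fisher = skalpha.fisher_alpha(counts)
    return [
        float(len(c)),
        float(skalpha.chao1(counts, bias_corrected=True)),
        float(shannon),
        float(simpson),
        float(inv_simpson),
        float(fisher),
    ]


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity: Observed, Chao1, Shannon, Simpson,
    InvSimpson and Fisher's alpha.

    Requires raw integer counts (Chao1's singleton/doubleton correction and
    Fisher's log-series fit are meaningless on proportions). Natural
    logarithms throughout; Chao1 uses the bias-corrected form
    ``S_obs + F1*(F1-1) / (2*(F2+1))``.
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        as_float = arr.astype(float)
        if not np.allclose(as_float, np.round(as_float)):
            raise ValueError("alpha diversity requires integer counts")
        arr = np.round(as_float).astype(int)
    if (arr < 0).any():
        raise ValueError("count table contains negative entries")
    rows = [_alpha_row(arr[i]) for i in range(arr.shape[0])]
    return pd.DataFrame(rows, index=counts.index, columns=ALPHA_METRICS)
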