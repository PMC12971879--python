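"""Univariate OLS association screening with Benjamini-Hochberg FDR.

Every (diet index, microbial outcome) pair gets its own ordinary-least-squares
model ``outcome ~ 1 + exposure`` (optionally plus covariates); raw two-sided
p-values are corrected across the whole test family with the
Benjamini-Hochberg step-up procedure. The result mirrors the structure of a
published screening table: slope, 95% CI, raw p, FDR q, and significance
flags at both thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OlsFit",
    "ols_fit",
    "bh_fdr",
    "screen_associations",
    "spearman_corr",
]


class OlsFit:
    """Coefficients, standard errors, 95% CIs and p-values of one OLS fit.

    Attributes are indexed by term name (``const``, the exposure name, then
    covariates). ``n_used`` counts the complete-case rows actually fitted.
    """

    def __init__(self, params, bse, ci95, pvalues, n_used, df_resid):
        self.params = params
        self.bse = bse
        self.ci95 = ci95
        self.pvalues = pvalues
        self.n_used = n_used
        self.df_resid = df_resid


def ols_fit(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    x_name: str = "x",
) -> OlsFit:
    """Fit ``y ~ 1 + x (+ covariates)`` by OLS on complete cases.

    Returns coefficient estimates solving the least-squares normal equations,
    classical standard errors, two-sided t-test p-values, and 95% CIs
    ``beta +/- t(0.975, df) * SE``. Raises on rank-deficient designs (naming
    the offending column) and when n is too small for the dof.
    """
    y = pd.Series(np.asarray(y, dtype=float), name="y")
    x = pd.Series(np.asarray(x, dtype=float), name=x_name)
    design = pd.DataFrame({x_name: x})
    if covariates is not None:
        cov = pd.DataFrame(np.asarray(covariates, dtype=float))
        cov.columns = [f"c{i}" for i in range(cov.shape[1])] if not isinstance(
            covariates, pd.DataFrame
        ) else list(covariates.columns)
        design = pd.concat([design, cov.reset_index(drop=True)], axis=1)

    frame = pd.concat([y.reset_index(drop=True), design.reset_index(drop=True)], axis=1)
    frame = frame.dropna()
    n = len(frame)
    p = design.shape[1] + 1
    if n <= p + 1:
        raise ValueError(f"too few complete cases (n={n}) for {p} coefficients")

    X = sm.add_constant(frame.iloc[:, 1:], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a dependent column by leave-one-out rank
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank:
                raise ValueError(f"rank-deficient design: column {col!r} is collinear")
        raise ValueError("rank-deficient design")
    res = sm.OLS(frame.iloc[:, 0], X).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["low", "high"]
    return OlsFit(res.params, res.bse, ci, res.pvalues, n, res.df_resid)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    ``q_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the ascending
    p-values, mapped back to the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_associations(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    family: str = "joint",
) -> pd.DataFrame:
    """Screen every (exposure, outcome) pair with univariate OLS.

    ``scores`` holds standardized diet indices (columns = exposures) and
    ``outcomes`` CLR taxa and/or standardized diversity metrics; rows align on
    subject id and only the shared subjects are used. The FDR family is
    ``"joint"`` (one family across all pairs, the default) or
    ``"per-exposure"``. Output rows are ordered by (exposure, outcome)
    alphabetically and carry ``beta``, ``ci_low``/``ci_high``, ``p_raw``,
    ``q_fdr``, ``n``, and significance flags at raw p<0.05 and q<0.05.
    """
    if family not in ("joint", "per-exposure"):
        raise ValueError(f"unknown FDR family {family!r}")
    shared = scores.index.intersection(outcomes.index)
    if len(shared) == 0:
        raise ValueError("no shared subject ids between scores and outcomes")
    scores = scores.loc[shared]
    outcomes = outcomes.loc[shared]
    cov = covariates.loc[shared] if covariates is not None else None

    rows = []
    for exposure in sorted(scores.columns):
        for outcome in sorted(outcomes.columns):
            fit = ols_fit(
                outcomes[outcome].to_numpy(),
                scores[exposure].to_numpy(),
                covariates=cov,
                x_name="exposure",
            )
            rows.append(
                {
                    "exposure": exposure,
                    "outcome": outcome,
                    "beta": fit.params["exposure"],
                    "ci_low": fit.ci95.loc["exposure", "low"],
                    "ci_high": fit.ci95.loc["exposure", "high"],
                    "p_raw": fit.pvalues["exposure"],
                    "n": fit.n_used,
                }
            )
    table = pd.DataFrame(rows)
    if family == "joint":
        table["q_fdr"] = bh_fdr(table["p_raw"].to_numpy())
    else:
        table["q_fdr"] = np.nan
        for exposure, idx in table.groupby("exposure").groups.items():
            table.loc[idx, "q_fdr"] = bh_fdr(table.loc[idx, "p_raw"].to_numpy())
    table["sig_raw"] = table["p_raw"] < 0.05
    table["sig_fdr"] = table["q_fdr"] < 0.05
    table.attrs["family_size"] = len(table)
    return table


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
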