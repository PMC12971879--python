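"""Two-model causal mediation analysis with nonparametric bootstrap inference.

For an exposure X (a standardized diet score), a candidate mediator M (a CLR
maternal taxon or maternal diversity metric), an outcome Y (a CLR infant
taxon or infant diversity metric) and optional covariates C (delivery mode by
default), two OLS models are fit on the same complete-case rows:

    mediator model:  M = alpha1 + a*X + beta2*C + e1
    outcome model:   Y = alpha2 + c'*X + b*M + beta4*C + e2

The indirect effect is the product a*b, and the total effect c' + a*b, which
in this linear two-model framework equals the slope of the reduced model
Y ~ 1 + X + C exactly. Inference on the indirect effect resamples dyads
(rows) with replacement, refits both models per replicate, and reports the
percentile confidence interval and a two-tailed pseudo p-value (twice the
smaller tail fraction of the bootstrap draws around zero, floored at 1/B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import ols_fit

__all__ = [
    "MediationSpec",
    "BootstrapSummary",
    "MediationResult",
    "indirect_effect",
    "sobel_se",
    "fit_mediation",
    "bootstrap_mediation",
    "rank_mediators",
    "run_cma_suite",
]


@dataclass
class MediationSpec:
    """Names and inference settings for one mediation fit."""

    exposure: str = "exposure"
    mediator: str = "mediator"
    outcome: str = "outcome"
    covariates: tuple[str, ...] = ("delivery_mode",)
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if len({self.exposure, self.mediator, self.outcome}) != 3:
            raise ValueError("exposure, mediator and outcome must be distinct")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class BootstrapSummary:
    """Percentile CI and pseudo p-value of the bootstrap indirect draws."""

    n_draws: int
    ci: tuple[float, float]
    pseudo_p: float
    sd: float
    n_degenerate: int = 0


@dataclass
class MediationResult:
    """Point estimates (and optional bootstrap summary) of one mediation fit."""

    exposure: str
    mediator: str
    outcome: str
    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    alpha1: float
    alpha2: float
    covariate_coefs_m: dict = field(default_factory=dict)
    covariate_coefs_y: dict = field(default_factory=dict)
    resid_var_m: float = float("nan")
    resid_var_y: float = float("nan")
    se_a: float = float("nan")
    se_b: float = float("nan")
    p_a: float = float("nan")
    p_b: float = float("nan")
    p_c_prime: float = float("nan")
    adjusted: bool = False
    n_used: int = 0
    bootstrap: BootstrapSummary | None = None


def indirect_effect(a: float, b: float) -> float:
    """Indirect (mediated) effect: the product of the a and b paths."""
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("path coefficients must be finite")
    return a * b


def sobel_se(a: float, se_a: float, b: float, se_b: float) -> float:
    """First-order delta-method standard error of the indirect effect a*b."""
    return float(np.sqrt(b * b * se_a * se_a + a * a * se_b * se_b))


def _complete_cases(x, m, y, covariates):
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
        cov_names: list[str] = []
    else:
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            cov_names = [f"c{i}" for i in range(cov.shape[1])]
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) & np.isfinite(cov).all(axis=1)
    x, m, y, cov = x[keep], m[keep], y[keep], cov[keep]
    # a constant covariate is collinear with the intercept and carries no
    # adjustment information: drop it, so adjusted == unadjusted exactly
    if cov.shape[1]:
        varying = np.ptp(cov, axis=0) > 0
        cov = cov[:, varying]
        cov_names = [n for n, v in zip(cov_names, varying) if v]
    return x, m, y, cov, cov_names


def fit_mediation(
    x,
    m,
    y,
    covariates=None,
    spec: MediationSpec | None = None,
) -> MediationResult:
    """Point estimates of the mediation paths on complete cases.

    Fits ``M ~ 1 + X + C`` (a-path) and ``Y ~ 1 + X + M + C`` (b- and
    c'-paths) by OLS on the same rows; indirect = a*b, total = c' + a*b.
    """
    if spec is None:
        spec = MediationSpec()
    xv, mv, yv, cov, cov_names = _complete_cases(x, m, y, covariates)
    n = xv.size
    if n <= 4 + cov.shape[1]:
        raise ValueError(f"too few complete cases (n={n}) for mediation")

    cov_df = pd.DataFrame(cov, columns=cov_names) if cov.shape[1] else None
    fit_m = ols_fit(mv, xv, covariates=cov_df, x_name="x")
    design_y = pd.DataFrame({"m": mv})
    if cov_df is not None:
        design_y = pd.concat([design_y, cov_df], axis=1)
    fit_y = ols_fit(yv, xv, covariates=design_y, x_name="x")

    a = float(fit_m.params["x"])
    b = float(fit_y.params["m"])
    c_prime = float(fit_y.params["x"])
    ab = indirect_effect(a, b)

    resid_m = mv - (fit_m.params["const"] + a * xv + (cov @ fit_m.params[cov_names].to_numpy() if cov_names else 0.0))
    resid_y = yv - (
        fit_y.params["const"]
        + c_prime * xv
        + b * mv
        + (cov @ fit_y.params[cov_names].to_numpy() if cov_names else 0.0)
    )
    return MediationResult(
        exposure=spec.exposure,
        mediator=spec.mediator,
        outcome=spec.outcome,
        a=a,
        b=b,
        c_prime=c_prime,
        indirect=ab,
        total=c_prime + ab,
        alpha1=float(fit_m.params["const"]),
        alpha2=float(fit_y.params["const"]),
        covariate_coefs_m={k: float(fit_m.params[k]) for k in cov_names},
        covariate_coefs_y={k: float(fit_y.params[k]) for k in cov_names},
        resid_var_m=float(resid_m @ resid_m / fit_m.df_resid),
        resid_var_y=float(resid_y @ resid_y / fit_y.df_resid),
        se_a=float(fit_m.bse["x"]),
        se_b=float(fit_y.bse["m"]),
        p_a=float(fit_m.pvalues["x"]),
        p_b=float(fit_y.pvalues["m"]),
        p_c_prime=float(fit_y.pvalues["x"]),
        adjusted=cov.shape[1] > 0,
        n_used=n,
    )


def _batched_paths(x, m, y, cov, idx):
    """a, b, c' for each bootstrap resample via batched normal equations.

    ``idx`` is (B, n) integer resample indices. Degenerate (near-singular)
    replicates return NaN paths.
    """
    B, n = idx.shape
    ones = np.ones((B, n, 1))
    xs = x[idx][..., None]
    ms = m[idx][..., None]
    covs = cov[idx] if cov.shape[1] else np.empty((B, n, 0))

    X1 = np.concatenate([ones, xs, covs], axis=2)
    X2 = np.concatenate([ones, xs, ms, covs], axis=2)

    a = np.full(B, np.nan)
    b = np.full(B, np.nan)
    cp = np.full(B, np.nan)
    for X, yvec, out in ((X1, m[idx], ("a",)), (X2, y[idx], ("cp", "b"))):
        XtX = np.einsum("bni,bnj->bij", X, X)
        Xty = np.einsum("bni,bn->bi", X, yvec)
        eig = np.linalg.eigvalsh(XtX)
        ok = eig[:, 0] > 1e-10 * eig[:, -1]
        beta = np.full((B, X.shape[2]), np.nan)
        if ok.any():
            beta[ok] = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
        if out == ("a",):
            a = beta[:, 1]
        else:
            cp = beta[:, 1]
            b = beta[:, 2]
    return a, b, cp


def bootstrap_mediation(
    x,
    m,
    y,
    covariates=None,
    spec: MediationSpec | None = None,
) -> MediationResult:
    """Mediation fit with bootstrap CI and pseudo p for the indirect effect.

    Dyads (rows) are resampled jointly with replacement ``spec.n_boot`` times
    and both models refit per replicate. Near-singular resamples (e.g. a
    constant covariate) are skipped and counted; more than 10% degenerate
    replicates aborts with diagnostics. Fixed ``spec.seed`` makes the CI and
    pseudo p deterministic.
    """
    if spec is None:
        spec = MediationSpec()
    result = fit_mediation(x, m, y, covariates=covariates, spec=spec)
    xv, mv, yv, cov, _ = _complete_cases(x, m, y, covariates)
    n = xv.size
    rng = np.random.default_rng(spec.seed)
    idx = rng.integers(0, n, size=(spec.n_boot, n))
    a_bs, b_bs, _ = _batched_paths(xv, mv, yv, cov, idx)
    ab = a_bs * b_bs
    good = np.isfinite(ab)
    n_deg = int(spec.n_boot - good.sum())
    if n_deg > 0.10 * spec.n_boot:
        raise RuntimeError(
            f"{n_deg}/{spec.n_boot} degenerate bootstrap replicates "
            f"(n={n}, covariate columns={cov.shape[1]}); data too unstable to resample"
        )
    draws = ab[good]
    alpha = 1.0 - spec.ci_level
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    frac_le = np.mean(draws <= 0)
    frac_ge = np.mean(draws >= 0)
    pseudo_p = max(2.0 * min(frac_le, frac_ge), 1.0 / spec.n_boot)
    result.bootstrap = BootstrapSummary(
        n_draws=int(good.sum()),
        ci=(float(lo), float(hi)),
        pseudo_p=float(min(pseudo_p, 1.0)),
        sd=float(draws.std(ddof=1)),
        n_degenerate=n_deg,
    )
    return result


def rank_mediators(results: list[MediationResult], k: int) -> list[MediationResult]:
    """Top-k results by |indirect effect|, descending; ties break by mediator
    name ascending."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not results:
        raise ValueError("no mediation results to rank")
    ordered = sorted(results, key=lambda r: (-abs(r.indirect), r.mediator))
    return ordered[:k]


def run_cma_suite(
    exposure: pd.Series,
    exposure_name: str,
    maternal_outcomes: pd.DataFrame,
    infant_outcome: pd.Series,
    outcome_name: str,
    delivery_mode: pd.Series,
    screen_table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, list[MediationResult]]:
    """Mediation suite for one exposure and one infant outcome.

    Candidate mediators are the maternal outcomes that were raw-significant
    (p < 0.05) for this exposure in the screening table. Each candidate gets
    an unadjusted and a delivery-mode-adjusted two-model bootstrap fit (each
    mediator separately; multiple mediators are never fit jointly). Returns a
    tidy table with one row per (mediator, adjustment) — empty, with the same
    columns, when there are no candidates — plus the result objects.
    """
    hits = screen_table[
        (screen_table["exposure"] == exposure_name)
        & (screen_table["p_raw"] < 0.05)
        & (screen_table["outcome"].isin(maternal_outcomes.columns))
    ]
    candidates = sorted(hits["outcome"].unique())

    shared = exposure.index.intersection(maternal_outcomes.index)
    shared = shared.intersection(infant_outcome.index).intersection(delivery_mode.index)
    x = exposure.loc[shared]
    y = infant_outcome.loc[shared]
    c = pd.DataFrame({"delivery_mode": delivery_mode.loc[shared].astype(float)})

    rows, results = [], []
    ss = np.random.SeedSequence(seed).spawn(max(1, 2 * len(candidates)))
    for i, mediator in enumerate(candidates):
        mvec = maternal_outcomes.loc[shared, mediator]
        for j, cov in enumerate((None, c)):
            spec = MediationSpec(
                exposure=exposure_name,
                mediator=mediator,
                outcome=outcome_name,
                covariates=() if cov is None else ("delivery_mode",),
                n_boot=n_boot,
                ci_level=ci_level,
                seed=int(ss[2 * i + j].generate_state(1)[0] % (2**31)),
            )
            res = bootstrap_mediation(x, mvec, y, covariates=cov, spec=spec)
            results.append(res)
            rows.append(
                {
                    "exposure": exposure_name,
                    "mediator": mediator,
                    "outcome": outcome_name,
                    "adjusted": res.adjusted,
                    "a": res.a,
                    "b": res.b,
                    "indirect": res.indirect,
                    "c_prime": res.c_prime,
                    "total": res.total,
                    "p_a": res.p_a,
                    "p_b": res.p_b,
                    "p_c_prime": res.p_c_prime,
                    "ci_low": res.bootstrap.ci[0],
                    "ci_high": res.bootstrap.ci[1],
                    "pseudo_p": res.bootstrap.pseudo_p,
                    "n": res.n_used,
                    "stars": "*" if res.bootstrap.pseudo_p < 0.05 else "",
                }
            )
    columns = [
        "exposure", "mediator", "outcome", "adjusted", "a", "b", "indirect",
        "c_prime", "total", "p_a", "p_b", "p_c_prime", "ci_low", "ci_high",
        "pseudo_p", "n", "stars",
    ]
    table = pd.DataFrame(rows, columns=columns)
    table.attrs["n_candidates"] = len(candidates)
    return table, results
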