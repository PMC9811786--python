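"""Phenotype construction and association models.

Covers the clinical classifiers (suicide-attempt severity from the Freeman
seriousness scale, depression risk groups from assessment probability
bands), binary logistic regression with Wald inference, the equal-variance
two-sample t-test, candidate-CpG vs stress-CpG regressions with
cross-cohort direction-consistency summaries, methylation-transcript
models, and Spearman correlation for blood-brain comparisons.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .discovery import bh_adjust
from .types import DawbaBand, FreemanAssessment, LogisticFitResult

log = logging.getLogger(__name__)

SEVERITY_CUTOFF = 6  # severe iff combined Freeman score strictly above this
HIGH_RISK_MIN_BAND = 4  # bands 4 (~50%) and 5 (>70%) are high risk


class SeparationError(RuntimeError):
    """Perfect or quasi-complete separation in a logistic fit."""


def classify_severity(a: FreemanAssessment) -> str:
    """"severe" iff combined score > 6, a violent method, or completed suicide."""
    if a.combined_score > SEVERITY_CUTOFF or a.violent_method or a.completed_suicide:
        return "severe"
    return "not_severe"


def classify_dawba_risk(b: DawbaBand) -> str:
    """"high" iff the band's nominal depression risk is at least ~50%."""
    return "high" if b.band >= HIGH_RISK_MIN_BAND else "low"


def fit_logistic(
    outcome: pd.Series | np.ndarray,
    design: pd.DataFrame,
    add_intercept: bool = True,
    profile_ci: bool = False,
    maxiter: int = 100,
) -> LogisticFitResult:
    """Maximum-likelihood binary logistic regression with Wald inference.

    Missing rows are dropped listwise (count logged).  Wald z = beta/SE from
    the inverse observed information, two-sided p from the standard normal,
    95% CI beta +/- 1.96 SE (or profile-likelihood with ``profile_ci``),
    exp(beta) reported as the odds ratio.  Raises :class:`SeparationError`
    on perfect/quasi separation instead of returning silent junk.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=design.index)
    X = design.copy()
    if add_intercept and "intercept" not in X.columns:
        X.insert(0, "intercept", 1.0)
    ok = ~(X.isna().any(axis=1) | y.isna())
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("fit_logistic: dropping %d rows with missing values", n_dropped)
    X, y = X.loc[ok], y.loc[ok]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        try:
            fit = model.fit(maxiter=maxiter, tol=1e-10)
        except Exception as exc:  # statsmodels raises PerfectSeparationError
            raise SeparationError(str(exc)) from exc
    params = fit.params
    se = fit.bse
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 25 or not np.all(
        np.isfinite(se)
    ):
        raise SeparationError("diverging coefficients indicate separation")
    z = params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    ci_low = params - 1.96 * se
    ci_high = params + 1.96 * se
    if profile_ci:
        bounds = [_profile_ci(model, fit, j) for j in range(len(params))]
        ci_low = pd.Series([b[0] for b in bounds], index=params.index)
        ci_high = pd.Series([b[1] for b in bounds], index=params.index)
    table = pd.DataFrame(
        {
            "beta": params,
            "se": se,
            "z": z,
            "p": p,
            "odds_ratio": np.exp(params),
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    )
    formula = f"{getattr(outcome, 'name', 'outcome')} ~ " + " + ".join(X.columns)
    return LogisticFitResult(
        table=table, n=int(ok.sum()), n_dropped=n_dropped, formula=formula
    )


def _profile_ci(model, fit, j, level=0.95):
    """Profile-likelihood CI by bisection on the profile deviance."""
    from scipy.optimize import brentq

    crit = stats.chi2.ppf(level, 1)
    beta_hat = np.asarray(fit.params)
    llf_hat = fit.llf
    exog = np.asarray(model.exog)
    endog = np.asarray(model.endog)
    others = [k for k in range(exog.shape[1]) if k != j]

    def profile_dev(c):
        offset = c * exog[:, j]
        if others:
            sub = sm.GLM(
                endog, exog[:, others], family=sm.families.Binomial(), offset=offset
            )
            llf = sub.fit(maxiter=200, tol=1e-10).llf
        else:
            mu = 1.0 / (1.0 + np.exp(-offset))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            llf = np.sum(endog * np.log(mu) + (1 - endog) * np.log(1 - mu))
        return 2.0 * (llf_hat - llf) - crit

    se_j = float(fit.bse.iloc[j])
    lo = hi = beta_hat[j]
    step = max(se_j, 1e-3)
    for _ in range(60):
        lo -= step
        if profile_dev(lo) > 0:
            break
    for _ in range(60):
        hi += step
        if profile_dev(hi) > 0:
            break
    return (
        brentq(profile_dev, lo, beta_hat[j], xtol=1e-8),
        brentq(profile_dev, beta_hat[j], hi, xtol=1e-8),
    )


def wald_summary(
    beta: float, se: float, ci_on_or_scale: bool = False
) -> dict[str, float]:
    """Wald arithmetic from a coefficient and its standard error."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    out = {"z": z, "p": p, "odds_ratio": float(np.exp(beta))}
    lo, hi = beta - 1.96 * se, beta + 1.96 * se
    if ci_on_or_scale:
        out["ci_low"], out["ci_high"] = float(np.exp(lo)), float(np.exp(hi))
    else:
        out["ci_low"], out["ci_high"] = lo, hi
    return out


def ttest_equal_var(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test with n1 + n2 - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def _ols_slope(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None):
    """OLS of y on [1, x, covariates]; returns slope, se, t, p for x."""
    n = y.size
    cols = [np.ones(n), x]
    if covariates is not None and covariates.size:
        cols.extend(np.atleast_2d(covariates.T))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    s2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * xtx_inv[1, 1])
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(beta[1]), float(se), float(t), float(p)


def cpg_cpg_association(
    candidate_m: pd.DataFrame,
    stress_m: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regress each candidate CpG's M value on each stress CpG + covariates.

    Inputs are probes x samples.  Returns one row per (candidate, stress)
    pair with beta, se, t, raw p, BH q within the cohort, and a nominal
    significance flag (raw p < 0.05).
    """
    samples = list(candidate_m.columns)
    cov = covariates.loc[samples].to_numpy(dtype=float) if covariates is not None else None
    rows = []
    for cand in candidate_m.index:
        y = candidate_m.loc[cand, samples].to_numpy(dtype=float)
        for sp in stress_m.index:
            x = stress_m.loc[sp, samples].to_numpy(dtype=float)
            b, se, t, p = _ols_slope(y, x, cov)
            rows.append(
                {"candidate": cand, "stress_cpg": sp, "beta": b, "se": se, "t": t,
                 "p_value": p}
            )
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_adjust(out["p_value"].to_numpy())
    out["nominal_significant"] = out["p_value"] < 0.05
    return out


def summarize_pair_consistency(per_cohort: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pool per-cohort pair tables and flag direction-consistent pairs.

    For each (candidate, stress) pair: counts cohorts with raw p < 0.05 and
    marks the pair consistent iff all nominally significant betas share the
    same sign.  A pair significant in a single cohort is trivially
    consistent.
    """
    if len(per_cohort) < 2:
        raise ValueError("need at least two cohorts")
    frames = []
    for cohort, tab in per_cohort.items():
        t = tab.copy()
        t["cohort"] = cohort
        frames.append(t)
    pooled = pd.concat(frames, ignore_index=True)
    records = []
    for (cand, sp), grp in pooled.groupby(["candidate", "stress_cpg"]):
        sig = grp[grp["p_value"] < 0.05]
        betas = sig["beta"].to_numpy()
        consistent = bool(betas.size) and (np.all(betas > 0) or np.all(betas < 0))
        records.append(
            {
                "candidate": cand,
                "stress_cpg": sp,
                "n_cohorts_significant": int(len(sig)),
                "direction_consistent": consistent,
                "betas_significant": list(betas),
                "cohorts_significant": list(sig["cohort"]),
            }
        )
    return pd.DataFrame(records)


def methylation_transcript_assoc(
    transcripts: pd.DataFrame,
    methylation_m: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regress each transcript on each CpG's M value (+ covariates).

    ``transcripts`` is samples x transcripts; ``methylation_m`` probes x
    samples.  BH across all tested (transcript, CpG) pairs.
    """
    samples = list(transcripts.index)
    cov = covariates.loc[samples].to_numpy(dtype=float) if covariates is not None else None
    rows = []
    for tr in transcripts.columns:
        y = transcripts[tr].to_numpy(dtype=float)
        for cpg in methylation_m.index:
            x = methylation_m.loc[cpg, samples].to_numpy(dtype=float)
            b, se, t, p = _ols_slope(y, x, cov)
            rows.append(
                {"transcript": tr, "probe_id": cpg, "beta": b, "se": se, "t": t,
                 "p_value": p}
            )
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_adjust(out["p_value"].to_numpy())
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    return float(stats.spearmanr(x, y).statistic)
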