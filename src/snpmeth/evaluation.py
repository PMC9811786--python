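"""Calibration and recovery studies over the synthetic cohorts.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns summary numbers: FDR control under the global
null, planted-truth recovery of cross-dependent CpGs, empirical-null
parameter recovery, agreement of the vectorized fits with brute-force OLS
oracles, logistic confidence-interval coverage, and deconvolution accuracy.
The worked-example helpers recompute printed Wald/FDR arithmetic and cohort
percentages from their published inputs.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import stats

from . import examples
from .discovery import (
    bh_adjust,
    discover_per_snp,
    estimate_empirical_null,
    fit_moderated_models,
    intersect_timepoints,
    significant_sets,
)
from .mqtl import scan_additive
from .phenotype import SeparationError, fit_logistic, wald_summary
from .preprocess import estimate_cell_proportions
from .simulate import SimulatorConfig, simulate_cohort
from .types import MethylationMatrix


def _null_config(seed: int, n_samples=200, n_probes=2000) -> SimulatorConfig:
    from .simulate import _default_probes

    return SimulatorConfig(
        n_samples=n_samples,
        n_probes=n_probes,
        probe_positions=_default_probes(n_probes),
        effect_table=[],
        seed=seed,
    )


def _planted_config(seed: int, n_samples=200, n_probes=2000) -> SimulatorConfig:
    from .simulate import _default_probes

    return SimulatorConfig(
        n_samples=n_samples,
        n_probes=n_probes,
        probe_positions=_default_probes(n_probes),
        seed=seed,  # default effect table: 3 cross-dependent CpGs, +0.8 M
    )


def _two_timepoint_crossdep(config_fn, seed: int, alpha=0.05):
    """Simulate screening + recall from one seed and intersect."""
    per_tp = {}
    frac_sig = []
    for tp, sub in (("screening", 0), ("recall", 1)):
        cfg = config_fn(seed * 2 + sub)
        cohort = simulate_cohort(cfg)
        per_snp = discover_per_snp(
            cohort.genotypes,
            cohort.methylation,
            cohort.covariates,
            fit_null=False,
        )
        sets = significant_sets(per_snp, alpha=alpha)
        per_tp[tp] = sets
        for tab in per_snp.values():
            frac_sig.append(float((tab["snp_adj_p"] < alpha).mean()))
    cds = intersect_timepoints(per_tp)
    return cds, float(np.mean(frac_sig))


def null_fdr_study(n_seeds=100, seed=0, alpha=0.05, n_samples=200, n_probes=2000):
    """FDR control under the global null across synthetic cohorts.

    Returns the mean fraction of probes with snp-adjusted p < alpha (with
    its Monte-Carlo SE) and the number of seeds whose longitudinal
    cross-dependent set is empty.
    """
    fracs, empty = [], 0
    for s in range(n_seeds):
        cds, frac = _two_timepoint_crossdep(
            lambda sd: _null_config(sd, n_samples, n_probes), seed * n_seeds + s, alpha
        )
        fracs.append(frac)
        empty += int(len(cds.longitudinal) == 0)
    fracs = np.asarray(fracs)
    return {
        "mean_sig_fraction": float(fracs.mean()),
        "mc_se": float(fracs.std(ddof=1) / np.sqrt(n_seeds)),
        "n_empty_crossdep": empty,
        "n_seeds": n_seeds,
    }


def planted_recovery_study(n_seeds=100, seed=0, alpha=0.05, n_samples=200, n_probes=2000):
    """Recovery of the three planted cross-dependent CpGs, zero tolerance
    for false positives: a seed succeeds iff the longitudinal set equals the
    planted set exactly."""
    truth = {pid for _, pid, _, _ in _planted_config(0).effect_table}
    n_exact = 0
    for s in range(n_seeds):
        cds, _ = _two_timepoint_crossdep(
            lambda sd: _planted_config(sd, n_samples, n_probes),
            seed * n_seeds + s,
            alpha,
        )
        n_exact += int(cds.longitudinal == truth)
    return {"n_exact_recovery": n_exact, "n_seeds": n_seeds, "n_planted": len(truth)}


def empirical_null_recovery(
    seed=0, n=20000, bias=0.3, inflation=1.2, signal_frac=0.05, signal_mean=4.0
):
    """Fit the empirical null to a contaminated normal and report estimates."""
    rng = np.random.default_rng(seed)
    n_sig = int(round(n * signal_frac))
    x = np.concatenate(
        [
            rng.normal(bias, inflation, n - n_sig),
            rng.normal(signal_mean, 1.0, n_sig),
        ]
    )
    null = estimate_empirical_null(x, seed=seed)
    return {
        "bias_true": bias,
        "bias_est": null.bias,
        "inflation_true": inflation,
        "inflation_est": null.inflation,
        "null_weight": null.weight,
        "n": n,
    }


def _ols_oracle(y, X):
    """Independent per-model OLS via normal equations (numpy lstsq)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def moderated_vs_ols_oracle(seed=0, n_probes=200, n_samples=60):
    """Max |difference| between vectorized moderated-model coefficients and a
    per-probe OLS oracle (coefficients are untouched by moderation)."""
    cfg = _planted_config(seed, n_samples=n_samples, n_probes=n_probes)
    cohort = simulate_cohort(cfg)
    covs = cohort.covariates
    from .discovery import code_dominant

    coded = code_dominant(cohort.genotypes.calls[cfg.variant_specs[0][0]])
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "snp": coded,
            "sex": covs["sex"],
            "age": covs["age"],
            "bmi": covs["bmi"],
            "batch": covs["batch"],
        },
        index=covs.index,
    )
    table, _ = fit_moderated_models(cohort.methylation, design, coef="snp")
    X = design.to_numpy(dtype=float)
    M = cohort.methylation.values.to_numpy(dtype=float)
    diffs = []
    for g in range(n_probes):
        beta, se, t, p, df = _ols_oracle(M[g], X)
        diffs.append(abs(beta[1] - table["coef"].iloc[g]))
    return {"max_abs_diff": float(np.max(diffs)), "n": n_probes}


def scan_vs_ols_oracle(seed=0, n_variants=20, n_probes=50, n_samples=120):
    """Max |difference| between the matrix mQTL scan and per-pair OLS."""
    rng = np.random.default_rng(seed)
    variants = [
        (f"rs{1000 + j}", "chr7", 1850000 + 500 * j, float(rng.uniform(0.1, 0.45)))
        for j in range(n_variants)
    ]
    probes = [(f"cg{j + 1:08d}", "chr7", 1850100 + 700 * j) for j in range(n_probes)]
    cfg = SimulatorConfig(
        n_samples=n_samples,
        variant_specs=tuple(variants),
        n_probes=n_probes,
        probe_positions=probes,
        effect_table=[(variants[0][0], probes[0][0], "additive", 0.6)],
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    covs = cohort.covariates[["sex", "age", "bmi", "batch"]]
    table = scan_additive(cohort.genotypes, cohort.methylation, covs)
    M = cohort.methylation.values
    X_cov = covs.to_numpy(dtype=float)
    max_diff = 0.0
    for _, row in table.iterrows():
        g = cohort.genotypes.calls[row["snp_id"]].to_numpy(dtype=float)
        y = M.loc[row["probe_id"]].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y)), g, X_cov])
        beta, se, t, p, df = _ols_oracle(y, X)
        max_diff = max(
            max_diff,
            abs(beta[1] - row["beta"]),
            abs(t[1] - row["t"]),
            abs(p[1] - row["p_value"]),
        )
    return {"max_abs_diff": float(max_diff), "n": int(len(table))}


def simulate_ski_like(seed: int, n=88, beta_meth=1.5):
    """One suicide-severity-style cohort: methylation, demographics, binary
    outcome generated with a known methylation coefficient."""
    rng = np.random.default_rng(seed)
    meth = rng.normal(0.0, 0.5, n)
    sex = rng.binomial(1, 0.65, n)
    age = rng.normal(34.0, 12.0, n)
    batch = rng.binomial(1, 0.5, n)
    pers = rng.binomial(1, 0.24, n)
    alc = rng.binomial(1, 0.19, n)
    eta = -0.62 + beta_meth * meth
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    design = pd.DataFrame(
        {
            "methylation_m": meth,
            "sex": sex,
            "age": (age - age.mean()) / age.std(),
            "batch": batch,
            "personality_disorder": pers,
            "alcohol_addiction": alc,
        }
    )
    return pd.Series(y, name="severity"), design


def logistic_coverage_study(n_reps=100, seed=0, beta_meth=1.5):
    """Wald 95% CI coverage of the planted methylation coefficient across
    simulated suicide-severity cohorts (n=88 each)."""
    covered = 0
    failures = 0
    for r in range(n_reps):
        y, design = simulate_ski_like(seed * n_reps + r, beta_meth=beta_meth)
        try:
            fit = fit_logistic(y, design)
        except SeparationError:
            failures += 1
            continue
        row = fit.coef("methylation_m")
        covered += int(row["ci_low"] <= beta_meth <= row["ci_high"])
    return {"n_covered": covered, "n_reps": n_reps, "n_separation": failures}


def deconvolution_recovery(seed=0, n_probes=500, n_samples=20, noise_sd=0.02):
    """Max absolute error of reference-based cell-proportion recovery."""
    rng = np.random.default_rng(seed)
    k = 6
    ref = pd.DataFrame(
        rng.normal(0.0, 2.0, (n_probes, k)),
        index=[f"cg{j + 1:08d}" for j in range(n_probes)],
        columns=[f"cell{c}" for c in range(k)],
    )
    w_true = rng.dirichlet(np.full(k, 4.0), size=n_samples)
    m = ref.to_numpy() @ w_true.T + rng.normal(0.0, noise_sd, (n_probes, n_samples))
    mat = MethylationMatrix(
        values=pd.DataFrame(
            m, index=ref.index, columns=[f"S{j + 1:04d}" for j in range(n_samples)]
        ),
        scale="M",
    )
    est, _ = estimate_cell_proportions(mat, ref)
    err = np.abs(est.to_numpy() - w_true).max()
    return {"max_abs_error": float(err), "n": n_samples}


def worked_example_wald():
    """Wald arithmetic on the published severity-model coefficient table."""
    tab = examples.SEVERITY_LOGISTIC_COEFS
    out = {}
    for name, row in tab.iterrows():
        s = wald_summary(row["beta"], row["se"])
        out[name] = {"odds_ratio": s["odds_ratio"], "z": s["z"], "p": s["p"]}
    return out


def worked_example_bh():
    """BH adjustment of the published transcript-model raw p-values."""
    return bh_adjust(np.asarray(examples.TRANSCRIPT_MODEL_RAW_P))


def cohort_count_summaries():
    """Group percentages and analytic sample size from published counts."""
    sev = examples.SEVERITY_GROUP_COUNTS
    risk = examples.RISK_GROUP_COUNTS
    return {
        "severe_pct": 100.0 * sev["severe"] / (sev["severe"] + sev["not_severe"]),
        "high_risk_pct": 100.0 * risk["high"] / (risk["high"] + risk["low"]),
        "analytic_n": examples.TRAUMA_COHORT_TOTAL - examples.TRAUMA_COHORT_MISSING,
    }
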