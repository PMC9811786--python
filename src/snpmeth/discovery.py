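"""Per-SNP epigenome-wide moderated linear models and CpG selection.

For each candidate SNP, every probe's M value is regressed on the
dominant-coded genotype plus sex, age, BMI and batch.  Residual variances
are shrunk toward an empirical-Bayes prior estimated by the method of
moments on the log sample variances (Fisher/digamma moment equations), and
moderated t statistics are referred to a Student t with augmented degrees
of freedom.  Raw p-values are corrected twice: Benjamini-Hochberg within a
SNP scan, then multiplied by the number of SNPs tested (clipped at 1).  An
empirical-null Gaussian mixture fitted to the moderated statistics yields a
bias (null mean) and inflation (null sd) estimate used to recompute
corrected statistics and p-values.

A probe significant (snp-adjusted p < alpha) for at least two SNPs within a
timepoint is "cross-dependent"; the longitudinal set intersects these
across timepoints.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import CrossDependentSet, EmpiricalNull, MethylationMatrix, ModerationPrior

log = logging.getLogger(__name__)


class MonomorphicVariantError(ValueError):
    pass


def code_dominant(calls: np.ndarray | pd.Series) -> np.ndarray:
    """Carrier coding with respect to the minor allele.

    0 -> 0, 1/2 -> 1 when the alternate allele is the minor one; if the
    alternate-allele frequency in the data exceeds 0.5 the coding flips so
    that "minor allele present" is what is coded.  Missing calls (negative)
    stay NaN.  Raises on monomorphic input.
    """
    x = np.asarray(calls, dtype=float)
    x = np.where(x < 0, np.nan, x)
    valid = x[~np.isnan(x)]
    if valid.size == 0:
        raise MonomorphicVariantError("no valid genotype calls")
    alt_freq = valid.sum() / (2 * valid.size)
    if alt_freq > 0.5:
        x = 2.0 - x
    coded = np.where(np.isnan(x), np.nan, (x >= 1).astype(float))
    uniq = np.unique(coded[~np.isnan(coded)])
    if uniq.size < 2:
        raise MonomorphicVariantError("variant is monomorphic under dominant coding")
    return coded


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Method-of-moments fit of the scaled-F prior on sample variances.

    Moments of log s^2 around digamma/trigamma of df/2 give the prior
    degrees of freedom d0 and prior variance s0^2; when the excess variance
    of log s^2 is non-positive the prior is degenerate (d0 = inf).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = np.exp(emean)
    return ModerationPrior(d0=float(d0), s0sq=float(s0sq))


def squeeze_variances(s2: np.ndarray, df: float, prior: ModerationPrior) -> np.ndarray:
    """Posterior variances (d0*s0^2 + df*s^2) / (d0 + df)."""
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0sq)
    return (prior.d0 * prior.s0sq + df * np.asarray(s2, dtype=float)) / (prior.d0 + df)


def fit_moderated_models(
    m: MethylationMatrix,
    design: pd.DataFrame,
    coef: str = "snp",
) -> tuple[pd.DataFrame, ModerationPrior]:
    """Moderated per-probe linear models over a shared design matrix.

    ``design`` is samples x predictors and must include an intercept column;
    ``coef`` names the predictor of interest (the coded SNP).  Rows with any
    missing predictor are dropped (listwise, logged).  Returns the
    association table (one row per probe: coef, se, df_residual, t, p_value,
    fdr_p) and the fitted variance prior.  Coefficients are identical to
    per-probe OLS; moderation only touches the variances and t/p.
    """
    if m.scale != "M":
        m = m.as_m()
    design = design.loc[m.sample_ids]
    ok = ~design.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropping %d samples with missing design values", n_dropped)
        design = design.loc[ok]
    X = design.to_numpy(dtype=float)
    Y = m.values[design.index].to_numpy(dtype=float).T  # samples x probes
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    df_resid = n - p
    if df_resid < 2:
        raise ValueError("need residual degrees of freedom >= 2")
    q, r = np.linalg.qr(X)
    coefs = np.linalg.solve(r, q.T @ Y)  # p x probes
    resid = Y - X @ coefs
    rss = (resid**2).sum(axis=0)
    s2 = rss / df_resid
    xtx_inv = np.linalg.inv(r.T @ r)
    j = list(design.columns).index(coef)
    unscaled = np.sqrt(xtx_inv[j, j])

    prior = estimate_variance_prior(s2, df_resid)
    s2_post = squeeze_variances(s2, df_resid, prior)
    se = np.sqrt(s2_post) * unscaled
    tstat = coefs[j] / se
    df_total = prior.d0 + df_resid
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    table = pd.DataFrame(
        {
            "coef": coefs[j],
            "ave_m": Y.mean(axis=0),
            "se": se,
            "df_residual": float(df_resid),
            "s2": s2,
            "t": tstat,
            "p_value": pvals,
            "fdr_p": bh_adjust(pvals),
        },
        index=pd.Index(m.probe_ids, name="probe_id"),
    )
    return table, prior


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, returned in the input
    order; tied p-values share a value.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def snp_count_adjust(q: np.ndarray, n_snps: int) -> np.ndarray:
    """Bonferroni across SNP scans: q * n_snps clipped at 1."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q-values must lie in [0, 1]")
    return np.minimum(q * n_snps, 1.0)


_LOG2PI = np.log(2.0 * np.pi)

#: minimum distance of the side-component means from the null mean, in null
#: standard deviations; keeps the tail components from absorbing the bulk
SIDE_SEPARATION = 2.0


def _em_fit(x, w, mu, sd, max_iter=500, tol=1e-8):
    """EM for the 3-component Gaussian mixture; component 0 is the null.

    Side-component means are projected to stay at least ``SIDE_SEPARATION``
    null-SDs away from the null mean, so on a pure Gaussian sample the side
    components model genuine tails rather than eroding the null scale.
    """
    n = x.size
    loglik = -np.inf
    for _ in range(max_iter):
        z = (x[None, :] - mu[:, None]) / sd[:, None]
        logd = (
            np.log(np.maximum(w[:, None], 1e-300))
            - 0.5 * z * z
            - np.log(sd[:, None])
            - 0.5 * _LOG2PI
        )
        mx = logd.max(axis=0)
        dens = np.exp(logd - mx)
        tot = dens.sum(axis=0)
        new_loglik = float((np.log(tot) + mx).sum())
        resp = dens / tot
        nk = resp.sum(axis=1)
        w = nk / n
        mu = (resp @ x) / np.maximum(nk, 1e-12)
        var = np.array(
            [(resp[k] @ (x - mu[k]) ** 2) / max(nk[k], 1e-12) for k in range(3)]
        )
        sd = np.sqrt(np.maximum(var, 1e-12))
        gap = SIDE_SEPARATION * sd[0]
        mu[1] = min(mu[1], mu[0] - gap)
        mu[2] = max(mu[2], mu[0] + gap)
        if new_loglik - loglik < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    return loglik, w, mu, sd


def estimate_empirical_null(
    statistics: np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> EmpiricalNull:
    """Fit the central null of a statistic vector by a 3-component mixture.

    A central Gaussian (the empirical null) plus one left and one right
    component capture the associated tails.  Initialization places the null
    at the median with MAD scale and the side components at +/- 2 MAD;
    ``n_restarts`` jittered restarts are run and the best-likelihood valid
    fit (null still central) is kept.  Returns the null mean (bias), null sd
    (inflation) and null weight.
    """
    x = np.asarray(statistics, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate statistic vector")
    if x.size < 1000:
        warnings.warn("fewer than 1000 statistics; empirical-null fit may be unstable")
    med = float(np.median(x))
    mad = float(stats.median_abs_deviation(x, scale="normal"))
    if mad == 0:
        mad = float(x.std()) or 1.0
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts + 1):
        if r == 0:
            mu = np.array([med, med - 2 * mad, med + 2 * mad])
            sd = np.array([mad, mad, mad])
            w = np.array([0.9, 0.05, 0.05])
        else:
            jit = rng.uniform(-0.5, 0.5, 3) * mad
            mu = np.array([med, med - 2 * mad, med + 2 * mad]) + jit
            sd = np.array([mad, mad, mad]) * np.exp(rng.uniform(-0.3, 0.3, 3))
            w0 = rng.uniform(0.7, 0.95)
            w = np.array([w0, (1 - w0) / 2, (1 - w0) / 2])
        loglik, w_f, mu_f, sd_f = _em_fit(x, w, mu, sd, max_iter=max_iter, tol=tol)
        # the null is the dominant component near the median; fall back to
        # the most central one if all components drifted (tiny panels)
        central = [k for k in range(3) if abs(mu_f[k] - med) <= 2 * mad]
        k0 = (
            max(central, key=lambda k: w_f[k])
            if central
            else int(np.argmin(np.abs(mu_f - med)))
        )
        if best is None or loglik > best[0]:
            best = (loglik, w_f[k0], mu_f[k0], sd_f[k0])
    _, w0, mu0, sd0 = best
    return EmpiricalNull(bias=float(mu0), inflation=float(sd0), weight=float(w0))


def apply_empirical_null(
    table: pd.DataFrame, null: EmpiricalNull, n_snps: int | None = None
) -> pd.DataFrame:
    """Recompute corrected statistics and p-values under the fitted null.

    corrected t = (t - bias) / inflation, two-sided p from the standard
    normal; FDR and (when ``n_snps`` is given) SNP-count adjustment are
    recomputed on the corrected p-values.
    """
    if null.inflation <= 0:
        raise ValueError("null inflation must be positive")
    out = table.copy()
    t_corr = (table["t"].to_numpy() - null.bias) / null.inflation
    p_corr = 2.0 * stats.norm.sf(np.abs(t_corr))
    out["t_corrected"] = t_corr
    out["p_corrected"] = p_corr
    out["fdr_p_corrected"] = bh_adjust(p_corr)
    out["bias"] = null.bias
    out["inflation"] = null.inflation
    if n_snps is not None:
        out["snp_adj_p_corrected"] = snp_count_adjust(out["fdr_p_corrected"], n_snps)
    return out


def discover_per_snp(
    genotypes,
    methylation: MethylationMatrix,
    covariates: pd.DataFrame,
    snp_ids: list[str] | None = None,
    alpha: float = 0.05,
    fit_null: bool = True,
    null_seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Run the full moderated scan for each candidate SNP.

    Covariates used: sex, age, bmi, batch (whichever are present).  Returns
    a SNP -> association table mapping; each table carries raw, FDR and
    SNP-count-adjusted p-values, and (when ``fit_null``) empirical-null
    corrected columns.  Monomorphic variants are skipped with a warning.
    """
    snp_ids = list(snp_ids or genotypes.variant_ids)
    n_snps = len(snp_ids)
    covs = covariates[[c for c in ("sex", "age", "bmi", "batch") if c in covariates]]
    results: dict[str, pd.DataFrame] = {}
    for snp in snp_ids:
        try:
            coded = code_dominant(genotypes.calls[snp])
        except MonomorphicVariantError as exc:
            warnings.warn(f"skipping {snp}: {exc}")
            continue
        design = covs.copy()
        design.insert(0, "snp", coded)
        design.insert(0, "intercept", 1.0)
        table, prior = fit_moderated_models(methylation, design, coef="snp")
        table["snp_adj_p"] = snp_count_adjust(table["fdr_p"], n_snps)
        if fit_null:
            null = estimate_empirical_null(table["t"].to_numpy(), seed=null_seed)
            table = apply_empirical_null(table, null, n_snps=n_snps)
        table.attrs["prior"] = prior
        table.attrs["snp"] = snp
        results[snp] = table
    return results


def significant_sets(
    per_snp: dict[str, pd.DataFrame], alpha: float = 0.05, column: str = "snp_adj_p"
) -> dict[str, set]:
    return {
        snp: set(tab.index[tab[column] < alpha]) for snp, tab in per_snp.items()
    }


def select_cross_dependent(per_snp_sig: dict[str, set], min_snps: int = 2) -> set:
    """Probes significant for at least ``min_snps`` SNPs within a timepoint."""
    counts: dict[str, int] = {}
    for probes in per_snp_sig.values():
        for p in probes:
            counts[p] = counts.get(p, 0) + 1
    return {p for p, c in counts.items() if c >= min_snps}


def intersect_timepoints(
    per_timepoint: dict[str, dict[str, set]], min_snps: int = 2
) -> CrossDependentSet:
    """Longitudinal cross-dependent CpGs: intersection of the per-timepoint
    multi-SNP sets, with full SNP/timepoint provenance retained."""
    if len(per_timepoint) < 2:
        raise ValueError("need at least two timepoints")
    multi = {
        tp: select_cross_dependent(sets, min_snps=min_snps)
        for tp, sets in per_timepoint.items()
    }
    longitudinal = set.intersection(*multi.values()) if multi else set()
    return CrossDependentSet(
        per_timepoint=per_timepoint,
        multi_snp=multi,
        longitudinal=longitudinal,
        min_snps=min_snps,
    )


#: export column order mirroring the published per-SNP association ledger
ASSOC_EXPORT_COLUMNS = {
    "coef": "logFC",
    "ave_m": "AveExpr",
    "t": "t",
    "p_value": "P.Value",
    "fdr_p": "adj.P.Val",
    "snp_adj_p": "adj.P.Val.SNP",
    "inflation": "Inflation",
    "bias": "Bias",
    "t_corrected": "T.corrected",
    "p_corrected": "P.corrected",
    "fdr_p_corrected": "adj.P.corrected",
    "snp_adj_p_corrected": "adj.P.SNP.corrected",
}


def write_assoc_table(table: pd.DataFrame, path, annotation: pd.DataFrame | None = None):
    """Write an association table as TSV with the published column names."""
    out = table.copy()
    if annotation is not None:
        for col in ("chrom", "pos", "gene"):
            if col in annotation.columns:
                out[col] = annotation.reindex(out.index)[col]
    cols = [c for c in ("chrom", "pos", "gene") if c in out.columns]
    cols += [c for c in ASSOC_EXPORT_COLUMNS if c in out.columns]
    out = out[cols].rename(columns=ASSOC_EXPORT_COLUMNS)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")
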