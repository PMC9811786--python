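"""Windowed additive-model mQTL scan over variant x probe pairs.

Variants are filtered to rs-identified, well-imputed (info >= 0.9),
common (A1 frequency in [0.1, 0.9]) sites inside a genomic window (the
default window covers the candidate gene +/- 10 kb on chr7).  The scan
regresses every probe's M value on allele dose plus covariates; it is
computed by residualizing methylation and dose on the covariates once and
taking cross-products, which is algebraically identical to per-pair OLS
(Frisch-Waugh-Lovell).  FDR is taken across all pairs of a scan; a
per-focus FDR is available for ranking tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import bh_adjust
from .types import GenotypeMatrix, MethylationMatrix

log = logging.getLogger(__name__)

NOT_IN_TABLE = "not in table"


@dataclass
class VariantFilterSpec:
    """Inclusion rules for scan variants (all bounds inclusive)."""

    info_min: float = 0.9
    a1_freq_range: tuple = (0.1, 0.9)
    window: tuple = ("chr7", 1845430, 2282580)  # chrom, start, end (1-based)

    def __post_init__(self):
        lo, hi = self.a1_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("a1_freq_range bounds must satisfy 0 <= lo <= hi <= 1")
        if self.window[1] > self.window[2]:
            raise ValueError("window start must not exceed end")


def filter_variants(
    meta: pd.DataFrame, spec: VariantFilterSpec
) -> tuple[list[str], dict]:
    """Apply the three variant filters plus the window; returns IDs + report."""
    for col in ("info", "a1_freq", "chrom", "pos"):
        if col not in meta.columns:
            raise ValueError(f"variant metadata lacks column {col!r}")
    report = {"no_rs_id": 0, "low_info": 0, "freq_out_of_range": 0, "out_of_window": 0}
    keep = []
    chrom, start, end = spec.window
    lo, hi = spec.a1_freq_range
    for vid, row in meta.iterrows():
        if not str(vid).startswith("rs"):
            report["no_rs_id"] += 1
        elif row["info"] < spec.info_min:
            report["low_info"] += 1
        elif not (lo <= row["a1_freq"] <= hi):
            report["freq_out_of_range"] += 1
        elif not (row["chrom"] == chrom and start <= row["pos"] <= end):
            report["out_of_window"] += 1
        else:
            keep.append(vid)
    return keep, report


def scan_additive(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    covariates: pd.DataFrame,
    variant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Additive-dose OLS for every (variant, probe) pair.

    Returns a long table (snp_id, probe_id, beta, t, p_value, fdr_q) sorted
    by raw p.  Dose is the 0/1/2 call (or fractional dosage when supplied);
    monomorphic variants are skipped and logged.  BH is computed over all
    pairs of the scan.
    """
    m = methylation.as_m()
    samples = [s for s in m.sample_ids if s in genotypes.calls.index]
    if len(samples) < covariates.shape[1] + 3:
        raise ValueError("too few shared samples for the covariate design")
    X = np.column_stack(
        [np.ones(len(samples)), covariates.loc[samples].to_numpy(dtype=float)]
    )
    variant_ids = list(variant_ids or genotypes.variant_ids)
    G = genotypes.calls.loc[samples, variant_ids].to_numpy(dtype=float)
    keep = []
    for j, vid in enumerate(variant_ids):
        if np.unique(G[:, j]).size < 2:
            log.warning("skipping monomorphic variant %s", vid)
        else:
            keep.append(j)
    variant_ids = [variant_ids[j] for j in keep]
    G = G[:, keep]
    Y = m.values[samples].to_numpy(dtype=float).T  # samples x probes

    # residualize on covariates once (FWL)
    beta_x, *_ = np.linalg.lstsq(X, np.column_stack([G, Y]), rcond=None)
    R = np.column_stack([G, Y]) - X @ beta_x
    Gr, Yr = R[:, : G.shape[1]], R[:, G.shape[1] :]
    denom = (Gr**2).sum(axis=0)  # per variant
    slope = (Gr.T @ Yr) / denom[:, None]  # variants x probes
    yss = (Yr**2).sum(axis=0)  # per probe
    rss = yss[None, :] - slope**2 * denom[:, None]
    df = len(samples) - X.shape[1] - 1
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / denom[:, None])
    tstat = slope / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)

    n_v, n_p = tstat.shape
    table = pd.DataFrame(
        {
            "snp_id": np.repeat(variant_ids, n_p),
            "probe_id": np.tile(m.probe_ids, n_v),
            "beta": slope.ravel(),
            "t": tstat.ravel(),
            "p_value": pvals.ravel(),
        }
    )
    table["fdr_q"] = bh_adjust(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def _partner_cols(records: pd.DataFrame, focus: str) -> tuple[str, str]:
    if focus in set(records["snp_id"]):
        return "snp_id", "probe_id"
    if focus in set(records["probe_id"]):
        return "probe_id", "snp_id"
    raise KeyError(f"unknown focus ID {focus!r}")


def rank_partners(
    records: pd.DataFrame,
    focus: str,
    k: int = 10,
    named_partners: list[str] | None = None,
    per_focus_fdr: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Rank a focus entity's partners by FDR.

    Sort key: q ascending, ties broken by \\|t\\| descending then partner ID.
    Returns the top-``k`` table (with 1-based ``rank``) and the placement of
    each requested named partner (or the "not in table" sentinel).  With
    ``per_focus_fdr`` the q-values are recomputed by BH over the focus
    entity's own pairs.
    """
    focus_col, partner_col = _partner_cols(records, focus)
    sub = records[records[focus_col] == focus].copy()
    if per_focus_fdr:
        sub["fdr_q"] = bh_adjust(sub["p_value"].to_numpy())
    sub["_abs_t"] = -sub["t"].abs()
    sub = sub.sort_values(
        ["fdr_q", "_abs_t", partner_col], kind="mergesort"
    ).drop(columns="_abs_t")
    sub["rank"] = np.arange(1, len(sub) + 1)
    placements = {}
    for name in named_partners or ():
        hit = sub.loc[sub[partner_col] == name, "rank"]
        placements[name] = int(hit.iloc[0]) if len(hit) else NOT_IN_TABLE
    return sub.head(k).reset_index(drop=True), placements


def heatmap_export(
    records: pd.DataFrame,
    variant_pos: pd.Series,
    probe_pos: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Dense -log10(p) and beta matrices ordered by genomic position.

    Rows are probes, columns variants; axis labels carry coordinates as
    ``id@pos``.  Pairs absent from the scan are NaN.
    """
    variants = variant_pos.sort_values().index
    probes = probe_pos.sort_values().index
    neglog = pd.DataFrame(np.nan, index=probes, columns=variants)
    beta = pd.DataFrame(np.nan, index=probes, columns=variants)
    piv_p = records.pivot_table(
        index="probe_id", columns="snp_id", values="p_value", aggfunc="first"
    )
    piv_b = records.pivot_table(
        index="probe_id", columns="snp_id", values="beta", aggfunc="first"
    )
    neglog.update(-np.log10(piv_p))
    beta.update(piv_b)
    coord = lambda ids, pos: [f"{i}@{int(pos[i])}" for i in ids]
    for df in (neglog, beta):
        df.index = pd.Index(coord(probes, probe_pos), name="probe_id@pos")
        df.columns = pd.Index(coord(variants, variant_pos), name="snp_id@pos")
    return {"neglog10_p": neglog, "beta": beta}
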