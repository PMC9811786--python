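"""Methylation QC, normalization, batch/cell adjustment and scale transforms.

The QC chain mirrors standard array practice: detection-p filtering of
samples (p < 5e-5 in more than 75% of a sample's probes) and probes
(p < 0.01 in more than 75% of samples), annotation-based probe removal
(sex chromosomes, non-CpG probes, missing values, polymorphic probes with
MAF > 5%, SNPs at the CpG/single-base-extension position, cross-reactive
probes), quantile normalization of beta values, and location(/scale) batch
adjustment.  Cell heterogeneity is handled by reference-based deconvolution
(constrained least squares against cell-type profiles) followed by
regression-based removal of the estimated proportions from the M values.

Modelling downstream happens on M values; beta values are the reporting
scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .types import CLIP_EPS, MethylationMatrix


class SingletonBatchError(ValueError):
    pass


def filter_samples_by_detection(
    mat: MethylationMatrix, p_thresh: float = 0.00005, frac: float = 0.75
) -> MethylationMatrix:
    """Retain samples whose fraction of probes with detection p < p_thresh
    strictly exceeds ``frac``.  Order preserved."""
    if mat.detection_p is None:
        raise ValueError("detection_p required for sample filtering")
    pass_frac = (mat.detection_p.to_numpy() < p_thresh).mean(axis=0)
    keep = [s for s, f in zip(mat.sample_ids, pass_frac) if f > frac]
    return mat.subset(samples=keep)


def filter_probes_by_detection(
    mat: MethylationMatrix, p_thresh: float = 0.01, frac: float = 0.75
) -> MethylationMatrix:
    """Retain probes detected (p < p_thresh) in more than ``frac`` of samples."""
    if mat.detection_p is None:
        raise ValueError("detection_p required for probe filtering")
    pass_frac = (mat.detection_p.to_numpy() < p_thresh).mean(axis=1)
    keep = [p for p, f in zip(mat.probe_ids, pass_frac) if f > frac]
    return mat.subset(probes=keep)


#: annotation rules in application order; first matching rule claims a probe
_ANNOTATION_RULES = (
    "sex_chromosome",
    "non_cpg",
    "missing_values",
    "snp_in_probe",
    "snp_at_cpg_or_sbe",
    "cross_reactive",
)


def filter_probes_by_annotation(
    mat: MethylationMatrix,
    annotation: pd.DataFrame,
    maf_thresh: float = 0.05,
    cross_reactive: set | list | None = None,
) -> tuple[MethylationMatrix, dict]:
    """Remove unreliable probes; returns filtered matrix + {rule: count}.

    Rules, in order: sex-chromosome probes; non-CpG probes; probes with any
    missing value; probes with an internal SNP of MAF strictly above
    ``maf_thresh``; probes with a SNP at the CpG or single-base-extension
    position; probes on the cross-reactive list.
    """
    cross_reactive = set(cross_reactive or ())
    missing_ann = set(mat.probe_ids) - set(annotation.index)
    if missing_ann:
        raise ValueError(f"unannotated probes: {sorted(missing_ann)[:5]}...")
    report = {rule: 0 for rule in _ANNOTATION_RULES}
    keep = []
    has_missing = mat.values.isna().any(axis=1)
    for pid in mat.probe_ids:
        row = annotation.loc[pid]
        if bool(row.get("is_sex_chrom", False)):
            report["sex_chromosome"] += 1
        elif not bool(row.get("is_cpg", True)):
            report["non_cpg"] += 1
        elif bool(has_missing[pid]):
            report["missing_values"] += 1
        elif float(row.get("snp_in_probe_maf", 0.0) or 0.0) > maf_thresh:
            report["snp_in_probe"] += 1
        elif bool(row.get("snp_at_cpg_or_sbe", False)):
            report["snp_at_cpg_or_sbe"] += 1
        elif pid in cross_reactive:
            report["cross_reactive"] += 1
        else:
            keep.append(pid)
    return mat.subset(probes=keep), report


def quantile_normalize(mat: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the mean empirical distribution.

    Each sample's sorted values are replaced by the across-sample mean of
    order statistics; within-sample ranks are preserved and ties receive the
    average of their tied target quantiles.
    """
    x = mat.values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    target = np.sort(x, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = target
        # average target quantiles over tied input values
        s = pd.Series(mapped)
        out[:, j] = s.groupby(col[np.arange(len(col))]).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return MethylationMatrix(values=values, scale=mat.scale, detection_p=mat.detection_p)


def beta_to_m(mat: MethylationMatrix) -> MethylationMatrix:
    """M = log2(beta / (1 - beta)); betas clipped to [eps, 1-eps] first."""
    if mat.scale != "beta":
        raise ValueError("input must be on the beta scale")
    b = mat.values.to_numpy(dtype=float)
    if (b <= 0).any() or (b >= 1).any():
        warnings.warn("beta values outside (0,1); clipping to [1e-6, 1-1e-6]")
    b = np.clip(b, CLIP_EPS, 1 - CLIP_EPS)
    m = np.log2(b / (1.0 - b))
    values = pd.DataFrame(m, index=mat.values.index, columns=mat.values.columns)
    return MethylationMatrix(values=values, scale="M", detection_p=mat.detection_p)


def m_to_beta(mat: MethylationMatrix) -> MethylationMatrix:
    """Inverse logit2: beta = 2^M / (2^M + 1), strictly inside (0, 1)."""
    if mat.scale != "M":
        raise ValueError("input must be on the M scale")
    m = mat.values.to_numpy(dtype=float)
    beta = 1.0 / (1.0 + np.exp2(-m))
    values = pd.DataFrame(beta, index=mat.values.index, columns=mat.values.columns)
    return MethylationMatrix(values=values, scale="beta", detection_p=mat.detection_p)


def adjust_batch_location_scale(
    mat: MethylationMatrix, batch: pd.Series | np.ndarray, shrink: bool = False
) -> MethylationMatrix:
    """Remove per-probe batch means (and optionally scales) from M values.

    The probe's grand mean is preserved.  With ``shrink``, per-batch scale
    estimates are squeezed toward their across-probe average with the same
    empirical-Bayes machinery used for variance moderation, then each batch
    is rescaled to the probe's pooled residual scale.
    """
    if mat.scale != "M":
        raise ValueError("batch adjustment operates on M values")
    batch = np.asarray(pd.Series(batch, index=mat.sample_ids))
    x = mat.values.to_numpy(dtype=float)
    levels, inv = np.unique(batch, return_inverse=True)
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise SingletonBatchError("every batch needs at least 2 samples")
    grand = x.mean(axis=1, keepdims=True)
    out = x.copy()
    if len(levels) == 1:
        return mat
    # per-probe per-batch means
    centered = np.empty_like(x)
    batch_var = np.empty((x.shape[0], len(levels)))
    for b in range(len(levels)):
        cols = inv == b
        mu = x[:, cols].mean(axis=1, keepdims=True)
        centered[:, cols] = x[:, cols] - mu
        batch_var[:, b] = ((x[:, cols] - mu) ** 2).sum(axis=1) / (counts[b] - 1)
    if shrink:
        from .discovery import estimate_variance_prior, squeeze_variances

        pooled_sd = np.sqrt(
            (centered**2).sum(axis=1) / (x.shape[1] - len(levels))
        )
        for b in range(len(levels)):
            prior = estimate_variance_prior(batch_var[:, b], counts[b] - 1)
            shrunk = squeeze_variances(batch_var[:, b], counts[b] - 1, prior)
            cols = inv == b
            scale = pooled_sd / np.sqrt(shrunk)
            centered[:, cols] = centered[:, cols] * scale[:, None]
    out = centered + grand
    values = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return MethylationMatrix(values=values, scale="M", detection_p=mat.detection_p)


def estimate_cell_proportions(
    mat: MethylationMatrix, reference: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Reference-based deconvolution by constrained least squares.

    Per sample, solves ``min ||m - R w||_2`` subject to ``w >= 0`` and
    ``sum(w) <= 1`` over the probes shared with the reference.  Returns the
    sample x cell-type proportion table and the per-sample residual norm.
    """
    shared = [p for p in mat.probe_ids if p in reference.index]
    k = reference.shape[1]
    if len(shared) < k:
        raise ValueError("fewer shared probes than cell types")
    R = reference.loc[shared].to_numpy(dtype=float)
    M = mat.values.loc[shared].to_numpy(dtype=float)
    RtR = R.T @ R
    w0 = np.full(k, 1.0 / k)
    props = np.empty((mat.values.shape[1], k))
    resid = np.empty(mat.values.shape[1])
    cons = {"type": "ineq", "fun": lambda w: 1.0 - w.sum(), "jac": lambda w: -np.ones_like(w)}
    bounds = [(0.0, 1.0)] * k
    for j in range(M.shape[1]):
        m = M[:, j]
        Rtm = R.T @ m
        res = optimize.minimize(
            lambda w: 0.5 * w @ RtR @ w - Rtm @ w,
            w0,
            jac=lambda w: RtR @ w - Rtm,
            bounds=bounds,
            constraints=[cons],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-14},
        )
        props[j] = np.clip(res.x, 0.0, None)
        resid[j] = np.linalg.norm(m - R @ props[j])
    out = pd.DataFrame(props, index=mat.sample_ids, columns=list(reference.columns))
    return out, pd.Series(resid, index=mat.sample_ids, name="residual_norm")


def adjust_cell_composition(
    mat: MethylationMatrix, proportions: pd.DataFrame
) -> MethylationMatrix:
    """Regress estimated cell proportions out of every probe's M values.

    Uses the K-1 free proportion columns (the last column is determined by
    the sum constraint); each probe keeps its grand mean.  Collinear columns
    are dropped with a warning.
    """
    if mat.scale != "M":
        raise ValueError("cell-composition adjustment operates on M values")
    if list(proportions.index) != mat.sample_ids:
        proportions = proportions.loc[mat.sample_ids]
    P = proportions.to_numpy(dtype=float)[:, :-1]  # K-1 free columns
    Pc = P - P.mean(axis=0, keepdims=True)
    # drop constant/collinear columns; proportions are O(1), so use an
    # absolute tolerance rather than one relative to the tiny singular values
    tol = 1e-8 * np.sqrt(Pc.shape[0])
    nonconst = [j for j in range(Pc.shape[1]) if np.linalg.norm(Pc[:, j]) > tol]
    Pc = Pc[:, nonconst]
    if Pc.shape[1] < P.shape[1] or np.linalg.matrix_rank(Pc, tol=tol) < Pc.shape[1]:
        warnings.warn("rank-deficient proportion design; dropping collinear columns")
        keep: list[int] = []
        for j in range(Pc.shape[1]):
            if np.linalg.matrix_rank(Pc[:, keep + [j]], tol=tol) == len(keep) + 1:
                keep.append(j)
        Pc = Pc[:, keep]
    if Pc.shape[1] == 0:
        return mat
    x = mat.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Pc, x.T, rcond=None)
    adjusted = x - (Pc @ beta).T
    values = pd.DataFrame(adjusted, index=mat.values.index, columns=mat.values.columns)
    return MethylationMatrix(values=values, scale="M", detection_p=mat.detection_p)
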