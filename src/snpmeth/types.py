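"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLIP_EPS = 1e-6


@dataclass
class GenotypeMatrix:
    """Integer genotype calls (samples x variants) plus variant metadata.

    ``meta`` is indexed by variant ID and carries chrom, pos, configured and
    realized MAF, imputation info score and A1 allele frequency.
    """

    calls: pd.DataFrame
    meta: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class MethylationMatrix:
    """Methylation values (probes x samples) on a tagged scale.

    ``scale`` is ``"beta"`` (fraction methylated, in (0,1)) or ``"M"``
    (log2 odds of methylation).  ``detection_p`` is an optional matrix of the
    same shape with per-entry detection p-values.
    """

    values: pd.DataFrame
    scale: str = "beta"
    detection_p: pd.DataFrame | None = None

    def __post_init__(self):
        if self.scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("probe and sample IDs must be unique")
        if self.detection_p is not None and self.detection_p.shape != self.values.shape:
            raise ValueError("detection_p shape must match values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, probes=None, samples=None) -> "MethylationMatrix":
        v = self.values
        d = self.detection_p
        if probes is not None:
            v = v.loc[probes]
            d = d.loc[probes] if d is not None else None
        if samples is not None:
            v = v[samples]
            d = d[samples] if d is not None else None
        return MethylationMatrix(values=v, scale=self.scale, detection_p=d)

    def as_m(self) -> "MethylationMatrix":
        from .preprocess import beta_to_m

        return self if self.scale == "M" else beta_to_m(self)

    def as_beta(self) -> "MethylationMatrix":
        from .preprocess import m_to_beta

        return self if self.scale == "beta" else m_to_beta(self)


@dataclass
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0sq scale."""

    d0: float
    s0sq: float

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0sq > 0:
            raise ValueError("s0sq must be positive")


@dataclass
class EmpiricalNull:
    """Central-null component of a statistic distribution.

    ``bias`` is the null mean, ``inflation`` the null standard deviation,
    ``weight`` the null mixing proportion.
    """

    bias: float
    inflation: float
    weight: float

    def __post_init__(self):
        if not self.inflation > 0:
            raise ValueError("inflation (null sd) must be positive")
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("null weight must be in (0, 1]")


@dataclass
class CrossDependentSet:
    """Per-timepoint SNP->probe significance sets with their intersections.

    ``multi_snp`` holds, per timepoint, the probes associated with at least
    ``min_snps`` SNPs; ``longitudinal`` is the intersection across
    timepoints.
    """

    per_timepoint: dict
    multi_snp: dict
    longitudinal: set
    min_snps: int = 2

    def provenance(self, probe: str) -> dict:
        """Which SNPs hit this probe at which timepoint."""
        return {
            tp: sorted(s for s, probes in snps.items() if probe in probes)
            for tp, snps in self.per_timepoint.items()
        }


@dataclass
class LogisticFitResult:
    """Coefficient table of a binary-outcome logistic model.

    ``table`` rows are coefficients with columns beta, se, z, p, odds_ratio,
    ci_low, ci_high (CI on the beta scale).
    """

    table: pd.DataFrame
    n: int
    n_dropped: int
    formula: str
    converged: bool = True

    def coef(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class FreemanAssessment:
    """Suicide-attempt seriousness assessment.

    Two 1-5 subscales (reversibility of the method, probability that the
    attempt could be interrupted) plus flags for a violent method and an
    eventually completed suicide.
    """

    reversibility: int
    interruption: int
    violent_method: bool = False
    completed_suicide: bool = False

    def __post_init__(self):
        for name in ("reversibility", "interruption"):
            v = getattr(self, name)
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"{name} must be an integer in 1..5")

    @property
    def combined_score(self) -> int:
        return self.reversibility + self.interruption


#: nominal depression-risk probability per assessment band
DAWBA_BAND_RISK = {0: "<0.1%", 1: "~0.5%", 2: "~3%", 3: "~15%", 4: "~50%", 5: ">70%"}


@dataclass
class DawbaBand:
    """Ordinal 0-5 depression-risk probability band."""

    band: int

    def __post_init__(self):
        if self.band not in DAWBA_BAND_RISK:
            raise ValueError("band must be an integer in 0..5")

    @property
    def nominal_risk(self) -> str:
        return DAWBA_BAND_RISK[self.band]
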