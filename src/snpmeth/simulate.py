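"""Synthetic-cohort simulator with known ground truth.

Generates everything the downstream stages consume: genotypes at a handful
of candidate SNPs (correlated within an LD block through a Gaussian copula),
a methylation matrix on the M scale with planted additive/dominant genetic
effects, cell-composition and batch structure, detection p-values, sample
covariates, a binary phenotype drawn through a logistic link, and transcript
levels linearly coupled to a probe's methylation.

The defaults emulate the structure of a small adolescent blood-methylation
cohort: six intronic candidate variants on chr7 at minor-allele frequencies
between 18% and 28%, a ~440 kb probe window around a single gene, six
leukocyte cell types with granulocytes dominating, two array batches, and a
low-prevalence binary psychiatric outcome.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .types import GenotypeMatrix, MethylationMatrix

CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")

#: candidate variants: (id, chrom, pos 1-based hg19-like, maf)
DEFAULT_VARIANTS = (
    ("rs56072378", "chr7", 2104364, 0.25),
    ("rs11772627", "chr7", 2109821, 0.18),
    ("rs3823624", "chr7", 2110346, 0.18),
    ("rs2056477", "chr7", 2079744, 0.28),
    ("rs11514731", "chr7", 2051503, 0.18),
    ("rs61409925", "chr7", 1971226, 0.18),
)

#: probe window on chr7 (gene coordinates +/- 10 kb)
DEFAULT_WINDOW = ("chr7", 1845430, 2282580)


def _default_probes(n_probes: int = 2000) -> list[tuple[str, str, int]]:
    chrom, start, end = DEFAULT_WINDOW
    pos = np.linspace(start, end, n_probes).astype(int)
    return [(f"cg{i + 1:08d}", chrom, int(p)) for i, p in enumerate(pos)]


def default_effects(probe_ids) -> list[tuple[str, str, str, float]]:
    """Three cross-dependent CpGs, each driven by two candidate SNPs.

    The planted probes sit at 5%, 45% and 75% of the probe panel; each gets
    a dominant effect of +0.8 M units from the two highest-MAF candidates.
    """
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    picks = sorted({probe_ids[int(n * f)] for f in (0.05, 0.45, 0.75)})
    out = []
    for probe in picks:
        for snp in ("rs56072378", "rs2056477"):
            out.append((snp, probe, "dominant", 0.8))
    return out


@dataclass
class SimulatorConfig:
    """Ground-truth parameters for one synthetic cohort.

    ``effect_table`` rows are (variant_id, probe_id, model, effect) where
    model is ``"additive"`` (per minor-allele copy) or ``"dominant"``
    (carrier indicator) and the effect is on the M scale per coded unit.
    """

    n_samples: int = 200
    variant_specs: tuple = DEFAULT_VARIANTS
    ld_rho: float = 0.3
    n_probes: int = 2000
    probe_positions: list = field(default_factory=_default_probes)
    effect_table: list | None = None  # None -> default_effects(probe panel)
    cell_alpha: tuple = (6.0, 4.0, 2.0, 2.0, 4.0, 22.0)
    cell_shift_sd: float = 0.5
    batch_probs: tuple = (0.58, 0.42)
    batch_shift_sd: float = 0.1
    sex_p: float = 0.7
    age_mean: float = 15.5
    age_sd: float = 0.6
    bmi_mean: float = 22.0
    bmi_sd: float = 3.4
    baseline_mean: float = 0.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    phenotype_betas: dict = field(default_factory=lambda: {"intercept": -2.0})
    transcript_gamma: dict | None = None  # transcript -> (probe, intercept, gamma, noise_sd)
    detection_fail_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for vid, _, _, maf in self.variant_specs:
            if not 0.0 < maf < 1.0:
                raise ValueError(f"MAF for {vid} must be in (0, 1)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if any(a <= 0 for a in self.cell_alpha):
            raise ValueError("cell_alpha must be strictly positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.detection_fail_rate < 1.0:
            raise ValueError("detection_fail_rate must be in [0, 1)")
        if self.effect_table is None:
            self.effect_table = default_effects(p[0] for p in self.probe_positions)
        if self.transcript_gamma is None:
            first = self.probe_positions[0][0]
            self.transcript_gamma = {"tr_0001": (first, 1.0, 0.25, 0.5)}
        probe_ids = {p[0] for p in self.probe_positions}
        variant_ids = {v[0] for v in self.variant_specs}
        for vid, pid, model, _ in self.effect_table:
            if vid not in variant_ids:
                raise ValueError(f"effect_table variant {vid} not in variant_specs")
            if pid not in probe_ids:
                raise ValueError(f"effect_table probe {pid} not in probe list")
            if model not in ("additive", "dominant"):
                raise ValueError(f"unknown genetic model {model!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage substream derived from the global seed."""
        # crc32 keyed substream: stable across processes (str hash is not)
        key = zlib.crc32(stream.encode()) % (2**31)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:04d}" for i in range(self.n_samples)]

    @property
    def probe_ids(self) -> list[str]:
        return [p[0] for p in self.probe_positions]


def simulate_genotypes(config: SimulatorConfig) -> GenotypeMatrix:
    """Draw genotype calls under Hardy-Weinberg with block LD.

    Each of the two allele copies is a thresholded latent Gaussian; within a
    chromosome block the latent variables share pairwise correlation
    ``ld_rho`` (equicorrelated Gaussian copula), so marginal allele
    frequencies match the configured MAFs exactly while genotypes at nearby
    variants are correlated.
    """
    rng = config.rng("genotypes")
    n = config.n_samples
    specs = list(config.variant_specs)
    calls = np.zeros((n, len(specs)), dtype=np.int64)
    chroms = sorted({s[1] for s in specs})
    for chrom in chroms:
        idx = [i for i, s in enumerate(specs) if s[1] == chrom]
        mafs = np.array([specs[i][3] for i in idx])
        cuts = ndtri(mafs)  # allele = 1 iff latent < Phi^{-1}(maf)
        rho = config.ld_rho
        for _copy in range(2):
            shared = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, len(idx)))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
            calls[:, idx] += (z < cuts).astype(np.int64)
    realized = calls.mean(axis=0) / 2.0
    meta = pd.DataFrame(
        {
            "variant_id": [s[0] for s in specs],
            "chrom": [s[1] for s in specs],
            "pos": [s[2] for s in specs],
            "maf": [s[3] for s in specs],
            "realized_maf": realized,
            "info": 1.0,
            "a1_freq": realized,
        }
    ).set_index("variant_id")
    values = pd.DataFrame(calls, index=config.sample_ids, columns=meta.index)
    return GenotypeMatrix(calls=values, meta=meta)


def simulate_covariates(config: SimulatorConfig) -> pd.DataFrame:
    rng = config.rng("covariates")
    n = config.n_samples
    return pd.DataFrame(
        {
            "sex": rng.binomial(1, config.sex_p, n),
            "age": rng.normal(config.age_mean, config.age_sd, n),
            "bmi": rng.normal(config.bmi_mean, config.bmi_sd, n),
            "batch": rng.choice(len(config.batch_probs), n, p=config.batch_probs),
        },
        index=config.sample_ids,
    )


def simulate_cell_proportions(config: SimulatorConfig) -> pd.DataFrame:
    """Dirichlet-distributed leukocyte proportions, one row per sample."""
    rng = config.rng("cells")
    alpha = np.asarray(config.cell_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("cell_alpha must be strictly positive")
    props = rng.dirichlet(alpha, size=config.n_samples)
    cols = CELL_TYPES[: len(alpha)] if len(alpha) <= len(CELL_TYPES) else [
        f"cell{k}" for k in range(len(alpha))
    ]
    return pd.DataFrame(props, index=config.sample_ids, columns=list(cols))


def _coded_dose(calls: np.ndarray, model: str) -> np.ndarray:
    if model == "dominant":
        return (calls >= 1).astype(float)
    return calls.astype(float)


def simulate_methylation(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    cell_props: pd.DataFrame,
    config: SimulatorConfig,
) -> MethylationMatrix:
    """Generate the M-value matrix (probes x samples) plus detection p-values.

    M = probe baseline + planted genetic effects + cell effects + batch shift
    + N(0, noise_sd).  Beta values follow by the inverse logit2 transform, so
    they are strictly inside (0, 1).  A fraction ``detection_fail_rate`` of
    entries receives a detection p-value above 0.01 (failure), the rest below.
    """
    if list(genotypes.calls.index) != list(covariates.index) or list(
        covariates.index
    ) != list(cell_props.index):
        raise ValueError("sample IDs of genotypes, covariates and cell_props differ")
    rng = config.rng("methylation")
    n, p = config.n_samples, len(config.probe_positions)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, p)
    cell_shift = rng.normal(0.0, config.cell_shift_sd, (p, cell_props.shape[1]))
    batch_shift = rng.normal(0.0, config.batch_shift_sd, (p, len(config.batch_probs)))

    m = np.tile(baseline, (n, 1))
    m += cell_props.to_numpy() @ cell_shift.T
    m += batch_shift.T[covariates["batch"].to_numpy()]
    probe_index = {pid: j for j, pid in enumerate(config.probe_ids)}
    for vid, pid, model, effect in config.effect_table:
        dose = _coded_dose(genotypes.calls[vid].to_numpy(), model)
        m[:, probe_index[pid]] += effect * dose
    m += rng.normal(0.0, config.noise_sd, (n, p))

    values = pd.DataFrame(m.T, index=config.probe_ids, columns=config.sample_ids)
    fail = rng.random((p, n)) < config.detection_fail_rate
    detp = np.where(fail, rng.uniform(0.011, 1.0, (p, n)), rng.uniform(0.0, 0.00004, (p, n)))
    detection = pd.DataFrame(detp, index=config.probe_ids, columns=config.sample_ids)
    return MethylationMatrix(values=values, scale="M", detection_p=detection)


def simulate_phenotype(
    methylation: MethylationMatrix,
    covariates: pd.DataFrame,
    config: SimulatorConfig,
) -> pd.Series:
    """Bernoulli outcome through a logistic link on named predictors.

    ``phenotype_betas`` maps predictor names ("intercept", a covariate
    column, or a probe ID whose M value enters the linear predictor) to
    coefficients; the ground truth stays in the config.
    """
    rng = config.rng("phenotype")
    mvals = methylation.as_m().values
    eta = np.zeros(config.n_samples)
    for name, beta in config.phenotype_betas.items():
        if name == "intercept":
            eta += beta
        elif name in covariates.columns:
            eta += beta * covariates[name].to_numpy()
        elif name in mvals.index:
            eta += beta * mvals.loc[name].to_numpy()
        else:
            raise KeyError(f"phenotype predictor {name!r} not found")
    y = rng.binomial(1, expit(eta))
    return pd.Series(y, index=covariates.index, name="phenotype")


def simulate_transcripts(
    methylation: MethylationMatrix, config: SimulatorConfig
) -> pd.DataFrame:
    """Transcript levels linearly coupled to a probe's M value."""
    rng = config.rng("transcripts")
    mvals = methylation.as_m().values
    out = {}
    for tid, (probe, intercept, gamma, sd) in config.transcript_gamma.items():
        if probe not in mvals.index:
            raise KeyError(f"transcript {tid} coupled to unknown probe {probe}")
        noise = rng.normal(0.0, sd, config.n_samples)
        out[tid] = intercept + gamma * mvals.loc[probe].to_numpy() + noise
    return pd.DataFrame(out, index=methylation.sample_ids)


@dataclass
class Cohort:
    """One fully simulated cohort plus its ground truth."""

    config: SimulatorConfig
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    cell_props: pd.DataFrame
    methylation: MethylationMatrix
    phenotype: pd.Series
    transcripts: pd.DataFrame


def simulate_cohort(config: SimulatorConfig) -> Cohort:
    genotypes = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    cells = simulate_cell_proportions(config)
    meth = simulate_methylation(genotypes, covariates, cells, config)
    pheno = simulate_phenotype(meth, covariates, config)
    trans = simulate_transcripts(meth, config)
    return Cohort(config, genotypes, covariates, cells, meth, pheno, trans)


def write_fixture(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk (VCF + TSVs + ground-truth JSON manifest).

    Round-trips losslessly through :mod:`snpmeth.io` readers: numeric TSVs
    are written with full repr precision.
    """
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "beta": outdir / "beta.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "annotation": outdir / "annotation.tsv",
        "covariates": outdir / "covariates.tsv",
        "cell_props": outdir / "cell_proportions.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "manifest": outdir / "ground_truth.json",
    }
    sio.write_vcf(cohort.genotypes, paths["vcf"])
    beta = cohort.methylation.as_beta()
    sio.write_probe_matrix(beta.values, paths["beta"])
    sio.write_probe_matrix(cohort.methylation.detection_p, paths["detection_p"])
    ann = pd.DataFrame(
        [
            {
                "probe_id": pid,
                "chrom": chrom,
                "pos": pos,
                "is_cpg": True,
                "is_sex_chrom": False,
                "snp_in_probe_maf": 0.0,
                "snp_at_cpg_or_sbe": False,
                "cross_reactive": False,
                "gene": "GENE1",
            }
            for pid, chrom, pos in cohort.config.probe_positions
        ]
    )
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    cov = cohort.covariates.copy()
    cov.index.name = "sample_id"
    cov.to_csv(paths["covariates"], sep="\t")
    cp = cohort.cell_props.copy()
    cp.index.name = "sample_id"
    cp.to_csv(paths["cell_props"], sep="\t")
    ph = cohort.phenotype.to_frame()
    ph.index.name = "sample_id"
    ph.to_csv(paths["phenotype"], sep="\t")
    tr = cohort.transcripts.copy()
    tr.index.name = "sample_id"
    tr.to_csv(paths["transcripts"], sep="\t")
    manifest = {
        "seed": cohort.config.seed,
        "n_samples": cohort.config.n_samples,
        "planted_effects": [
            {"variant_id": v, "probe_id": p, "model": m, "effect": e}
            for v, p, m, e in cohort.config.effect_table
        ],
        "phenotype_betas": cohort.config.phenotype_betas,
        "transcript_gamma": {
            k: {"probe": v[0], "intercept": v[1], "gamma": v[2], "noise_sd": v[3]}
            for k, v in cohort.config.transcript_gamma.items()
        },
        "config": {
            k: v
            for k, v in dataclasses.asdict(cohort.config).items()
            if isinstance(v, (int, float, str))
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
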