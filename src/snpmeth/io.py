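"""Readers and writers for the on-disk formats.

TSV matrices carry probes as rows (first column ``probe_id``, remaining
columns sample IDs); covariate-style tables are keyed by ``sample_id``.
Genotypes travel as VCFv4.2 with GT (and optionally DS) fields, read back
through cyvcf2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, MethylationMatrix

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    meta = genotypes.meta
    samples = genotypes.sample_ids
    lines = []
    contigs = sorted(meta["chrom"].unique())
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    header = (
        "##fileformat=VCFv4.2\n##source=snpmeth-simulator\n"
        + "\n".join(lines)
        + "\n"
        + '##INFO=<ID=RMAF,Number=1,Type=Float,Description="Realized minor allele frequency">\n'
        + '##INFO=<ID=INF,Number=1,Type=Float,Description="Imputation info score">\n'
        + '##INFO=<ID=AF1,Number=1,Type=Float,Description="A1 allele frequency">\n'
        + '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        + '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n'
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    # sort records by (chrom, pos) as VCF requires
    order = meta.sort_values(["chrom", "pos"]).index
    rows = []
    for vid in order:
        row = meta.loc[vid]
        calls = genotypes.calls[vid]
        info = (
            f"RMAF={row['realized_maf']:.6f};INF={row['info']:.3f};"
            f"AF1={row['a1_freq']:.6f}"
        )
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            str(vid),
            "A",
            "G",
            ".",
            "PASS",
            info,
            "GT:DS",
        ]
        fields += [f"{_GT_CODE[int(c)]}:{int(c)}" for c in calls]
        rows.append("\t".join(fields))
    path.write_text(header + "\n".join(rows) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, infos, af1s, rmafs, calls = [], [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        infos.append(float(var.INFO.get("INF", 1.0)))
        af1s.append(float(var.INFO.get("AF1", np.nan)))
        rmafs.append(float(var.INFO.get("RMAF", np.nan)))
        gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        g = np.where(gts == 3, 2, np.where(gts == 2, -1, gts)).astype(np.int64)
        calls.append(g)
    meta = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chroms,
            "pos": poss,
            "maf": rmafs,
            "realized_maf": rmafs,
            "info": infos,
            "a1_freq": af1s,
        }
    ).set_index("variant_id")
    mat = pd.DataFrame(np.array(calls).T, index=samples, columns=meta.index)
    return GenotypeMatrix(calls=mat, meta=meta)


def write_probe_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_probe_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col="probe_id", float_precision="round_trip"
    )


def read_methylation(
    beta_path: str | Path, detection_path: str | Path | None = None
) -> MethylationMatrix:
    beta = read_probe_matrix(beta_path)
    det = read_probe_matrix(detection_path) if detection_path else None
    return MethylationMatrix(values=beta, scale="beta", detection_p=det)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    if "probe_id" not in ann.columns:
        raise ValueError("annotation file must have a probe_id column")
    return ann.set_index("probe_id")


def read_probe_list(path: str | Path) -> list[str]:
    """One-column text file of probe IDs (e.g. a cross-reactive list)."""
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
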