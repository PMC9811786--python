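#!/usr/bin/env python
"""Windowed additive mQTL scan around the candidate gene.

Filters variants (rs ID, info >= 0.9, A1 frequency in [0.1, 0.9], window
chr7:1845430-2282580), scans every variant x probe pair with the additive
covariate-adjusted model, ranks each cross-dependent CpG's partner variants
by FDR, and exports position-ordered heatmap matrices.  Outputs under
results/mqtl/<timepoint>/.
"""

import json
from pathlib import Path

from snpmeth import io as sio
from snpmeth.mqtl import VariantFilterSpec, filter_variants, heatmap_export, rank_partners, scan_additive
from snpmeth.types import MethylationMatrix

COHORTS = Path("results/cohorts")
PRE = Path("results/preprocess")
OUT = Path("results/mqtl")


def main():
    crossdep = json.loads(
        (Path("results/discovery") / "cross_dependent.json").read_text()
    )["longitudinal"]
    spec = VariantFilterSpec()
    for timepoint in ("screening", "recall"):
        genotypes = sio.read_vcf(COHORTS / timepoint / "genotypes.vcf")
        meth = MethylationMatrix(
            values=sio.read_probe_matrix(PRE / timepoint / "m_values.tsv"), scale="M"
        )
        cov = sio.read_sample_table(COHORTS / timepoint / "covariates.tsv")
        keep, report = filter_variants(genotypes.meta, spec)
        shared = [s for s in meth.sample_ids if s in genotypes.calls.index]
        records = scan_additive(
            genotypes,
            meth.subset(samples=shared),
            cov.loc[shared, ["sex", "age", "bmi", "batch"]],
            variant_ids=keep,
        )
        dst = OUT / timepoint
        dst.mkdir(parents=True, exist_ok=True)
        records.to_csv(dst / "mqtl.tsv", sep="\t", index=False)
        n_sig = int((records["fdr_q"] < 0.05).sum())
        print(
            f"{timepoint}: {len(keep)} variants x {len(meth.probe_ids)} probes, "
            f"{n_sig} pairs at q<0.05 (filter report: {report})"
        )
        ann = sio.read_annotation(COHORTS / timepoint / "annotation.tsv")
        mats = heatmap_export(
            records, genotypes.meta.loc[keep, "pos"], ann.loc[meth.probe_ids, "pos"]
        )
        for name, df in mats.items():
            df.to_csv(dst / f"heatmap_{name}.tsv", sep="\t")
        for probe in crossdep:
            top, placement = rank_partners(
                records, probe, k=10, named_partners=list(genotypes.variant_ids)
            )
            top.to_csv(dst / f"rank_{probe}.tsv", sep="\t", index=False)
            best = top.iloc[0]
            print(
                f"  {probe}: top partner {best['snp_id']} (q={best['fdr_q']:.2e}); "
                f"candidate-SNP placements: {placement}"
            )


if __name__ == "__main__":
    main()
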