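#!/usr/bin/env python
"""Phenotype association models for the cross-dependent CpGs.

Fits the binary logistic model phenotype ~ methylation + sex + age + BMI +
batch for each cross-dependent CpG at each timepoint (Wald inference, odds
ratios), plus the published-coefficient worked example (Wald arithmetic on
the printed severity-model table).  Writes coefficient tables under
results/phenotype/.
"""

import json
from pathlib import Path

import pandas as pd

from snpmeth import io as sio
from snpmeth.evaluation import worked_example_wald
from snpmeth.phenotype import fit_logistic
from snpmeth.types import MethylationMatrix

COHORTS = Path("results/cohorts")
PRE = Path("results/preprocess")
OUT = Path("results/phenotype")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    crossdep = json.loads(
        (Path("results/discovery") / "cross_dependent.json").read_text()
    )["longitudinal"]
    for timepoint in ("screening", "recall"):
        meth = MethylationMatrix(
            values=sio.read_probe_matrix(PRE / timepoint / "m_values.tsv"), scale="M"
        )
        cov = sio.read_sample_table(COHORTS / timepoint / "covariates.tsv")
        pheno = sio.read_sample_table(COHORTS / timepoint / "phenotype.tsv")["phenotype"]
        rows = []
        for probe in crossdep:
            design = pd.DataFrame(
                {
                    "methylation_m": meth.values.loc[probe, cov.index],
                    "sex": cov["sex"],
                    "age": cov["age"],
                    "bmi": cov["bmi"],
                    "batch": cov["batch"],
                }
            )
            fit = fit_logistic(pheno, design)
            row = fit.coef("methylation_m")
            rows.append(
                {
                    "probe": probe,
                    "beta": row["beta"],
                    "se": row["se"],
                    "z": row["z"],
                    "p": row["p"],
                    "odds_ratio": row["odds_ratio"],
                    "n": fit.n,
                }
            )
            print(
                f"{timepoint} {probe}: OR={row['odds_ratio']:.3f} "
                f"(z={row['z']:+.2f}, p={row['p']:.3f}, n={fit.n})"
            )
        pd.DataFrame(rows).to_csv(OUT / f"logistic_{timepoint}.tsv", sep="\t", index=False)

    worked = worked_example_wald()
    pd.DataFrame(worked).T.to_csv(OUT / "worked_example_wald.tsv", sep="\t")
    m = worked["methylation_m"]
    print(
        f"worked example (published severity model): methylation OR="
        f"{m['odds_ratio']:.3f}, z={m['z']:.3f}, p={m['p']:.4f}"
    )


if __name__ == "__main__":
    main()
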