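#!/usr/bin/env python
"""Generate the synthetic screening and recall cohorts.

Writes two fully specified cohorts (genotypes as VCF, beta values, detection
p-values, probe annotation, covariates, cell proportions, phenotype and
transcripts as TSV, plus the ground-truth manifest) under
results/cohorts/<timepoint>/.  Both cohorts share the candidate-variant
panel and planted cross-dependent CpGs but have independent sampling noise,
emulating the screening/recall design.
"""

import json
from pathlib import Path

from snpmeth.simulate import SimulatorConfig, simulate_cohort, write_fixture

OUT = Path("results/cohorts")
SEED = 1


def main():
    for offset, timepoint in enumerate(("screening", "recall")):
        cfg = SimulatorConfig(seed=SEED * 2 + offset)
        cohort = simulate_cohort(cfg)
        paths = write_fixture(cohort, OUT / timepoint)
        truth = json.loads(paths["manifest"].read_text())
        planted = {e["probe_id"] for e in truth["planted_effects"]}
        print(
            f"{timepoint}: n={cfg.n_samples} samples, {len(cfg.probe_ids)} probes, "
            f"{len(cfg.variant_specs)} variants; planted cross-dependent CpGs: "
            f"{sorted(planted)}"
        )
        print(f"  realized MAFs: "
              + ", ".join(f"{v}={m:.3f}" for v, m in
                          cohort.genotypes.meta["realized_maf"].items()))


if __name__ == "__main__":
    main()
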