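#!/usr/bin/env python
"""Quality control and normalization of the simulated methylation data.

Applies the detection-p sample/probe filters, annotation-based probe
removal, quantile normalization of beta values, conversion to M values,
batch location adjustment and regression-based cell-composition adjustment;
writes the adjusted M matrices and the per-rule removal reports under
results/preprocess/<timepoint>/.
"""

import json
from pathlib import Path

from snpmeth import io as sio
from snpmeth.preprocess import (
    adjust_batch_location_scale,
    adjust_cell_composition,
    beta_to_m,
    filter_probes_by_annotation,
    filter_probes_by_detection,
    filter_samples_by_detection,
    quantile_normalize,
)

IN = Path("results/cohorts")
OUT = Path("results/preprocess")


def main():
    for timepoint in ("screening", "recall"):
        src = IN / timepoint
        meth = sio.read_methylation(src / "beta.tsv", src / "detection_p.tsv")
        ann = sio.read_annotation(src / "annotation.tsv")
        cov = sio.read_sample_table(src / "covariates.tsv")
        cells = sio.read_sample_table(src / "cell_proportions.tsv")

        n0_samples, n0_probes = len(meth.sample_ids), len(meth.probe_ids)
        meth = filter_samples_by_detection(meth)
        meth = filter_probes_by_detection(meth)
        meth, report = filter_probes_by_annotation(meth, ann)
        meth = quantile_normalize(meth)
        m = beta_to_m(meth)
        m = adjust_batch_location_scale(m, cov.loc[m.sample_ids, "batch"])
        m = adjust_cell_composition(m, cells.loc[m.sample_ids])

        dst = OUT / timepoint
        dst.mkdir(parents=True, exist_ok=True)
        sio.write_probe_matrix(m.values, dst / "m_values.tsv")
        (dst / "filter_report.json").write_text(json.dumps(report, indent=2))
        print(
            f"{timepoint}: {n0_samples}->{len(m.sample_ids)} samples, "
            f"{n0_probes}->{len(m.probe_ids)} probes after QC; "
            f"annotation removals: { {k: v for k, v in report.items() if v} or 'none'}"
        )


if __name__ == "__main__":
    main()
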