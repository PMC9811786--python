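"""Pipeline orchestration: simulate -> preprocess -> discover -> mqtl ->
phenotype -> report, from a single config with deterministic seeding.

Every stage writes its outputs plus a JSON manifest (parameters, seed,
input-file SHA256 hashes, package version) into its own subdirectory; the
report stage aggregates the cross-dependent CpG list with provenance, the
mQTL rankings and the phenotype model table.  Stages communicate only
through their declared files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as sio
from .discovery import discover_per_snp, intersect_timepoints, significant_sets, write_assoc_table
from .mqtl import VariantFilterSpec, filter_variants, heatmap_export, rank_partners, scan_additive
from .phenotype import fit_logistic
from .preprocess import (
    adjust_batch_location_scale,
    adjust_cell_composition,
    beta_to_m,
    filter_probes_by_annotation,
    filter_probes_by_detection,
    filter_samples_by_detection,
    quantile_normalize,
)
from .simulate import SimulatorConfig, simulate_cohort, write_fixture

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "discover", "mqtl", "phenotype", "report")
TIMEPOINTS = ("screening", "recall")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    alpha: float = 0.05
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulate: dict = field(default_factory=dict)  # SimulatorConfig overrides
    fit_null: bool = True
    mqtl_window: tuple = ("chr7", 1845430, 2282580)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            if k == "stages":
                cfg.stages.update(v)
            elif k == "mqtl_window":
                cfg.mqtl_window = tuple(v)
            else:
                setattr(cfg, k, v)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, params: dict, inputs: list[Path], seed):
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _simulator_config(config: PipelineConfig, timepoint_offset: int) -> SimulatorConfig:
    kwargs = dict(config.simulate)
    if "n_probes" in kwargs and "probe_positions" not in kwargs:
        from .simulate import _default_probes

        kwargs["probe_positions"] = _default_probes(kwargs["n_probes"])
    kwargs["seed"] = config.seed * 2 + timepoint_offset
    return SimulatorConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns {stage: output dir}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    done: dict[str, Path] = {}
    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            log.info("stage %s disabled", stage)
            continue
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        log.info("running stage %s", stage)
        try:
            _RUNNERS[stage](config, stage_dir, state)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        done[stage] = stage_dir
    return done


def _stage_simulate(config, stage_dir, state):
    for off, tp in enumerate(TIMEPOINTS):
        cfg = _simulator_config(config, off)
        cohort = simulate_cohort(cfg)
        tp_dir = stage_dir / tp
        write_fixture(cohort, tp_dir)
        state[("cohort", tp)] = cohort
    _write_manifest(stage_dir, "simulate", dict(config.simulate), [], config.seed)


def _stage_preprocess(config, stage_dir, state):
    for tp in TIMEPOINTS:
        sim_dir = Path(config.outdir) / "simulate" / tp
        meth = sio.read_methylation(sim_dir / "beta.tsv", sim_dir / "detection_p.tsv")
        ann = sio.read_annotation(sim_dir / "annotation.tsv")
        cov = sio.read_sample_table(sim_dir / "covariates.tsv")
        cells = sio.read_sample_table(sim_dir / "cell_proportions.tsv")
        meth = filter_samples_by_detection(meth)
        meth = filter_probes_by_detection(meth)
        meth, report = filter_probes_by_annotation(meth, ann)
        meth = quantile_normalize(meth)
        m = beta_to_m(meth)
        m = adjust_batch_location_scale(m, cov.loc[m.sample_ids, "batch"])
        m = adjust_cell_composition(m, cells.loc[m.sample_ids])
        tp_dir = stage_dir / tp
        tp_dir.mkdir(exist_ok=True)
        sio.write_probe_matrix(m.values, tp_dir / "m_values.tsv")
        (tp_dir / "filter_report.json").write_text(json.dumps(report, indent=2))
        state[("m", tp)] = m
        state[("cov", tp)] = cov.loc[m.sample_ids]
        state[("ann", tp)] = ann
    inputs = [
        Path(config.outdir) / "simulate" / tp / f
        for tp in TIMEPOINTS
        for f in ("beta.tsv", "detection_p.tsv", "annotation.tsv", "covariates.tsv")
    ]
    _write_manifest(stage_dir, "preprocess", {}, inputs, config.seed)


def _stage_discover(config, stage_dir, state):
    per_tp_sets = {}
    for tp in TIMEPOINTS:
        sim_dir = Path(config.outdir) / "simulate" / tp
        genotypes = sio.read_vcf(sim_dir / "genotypes.vcf")
        m = state[("m", tp)]
        cov = state[("cov", tp)]
        shared = [s for s in m.sample_ids if s in genotypes.calls.index]
        per_snp = discover_per_snp(
            genotypes,
            m.subset(samples=shared),
            cov.loc[shared],
            alpha=config.alpha,
            fit_null=config.fit_null,
            null_seed=config.seed,
        )
        tp_dir = stage_dir / tp
        tp_dir.mkdir(exist_ok=True)
        ann = state.get(("ann", tp))
        for snp, tab in per_snp.items():
            write_assoc_table(tab, tp_dir / f"assoc_{snp}.tsv", annotation=ann)
        per_tp_sets[tp] = significant_sets(per_snp, alpha=config.alpha)
        state[("genotypes", tp)] = genotypes
    cds = intersect_timepoints(per_tp_sets)
    state["crossdep"] = cds
    summary = {
        "longitudinal": sorted(cds.longitudinal),
        "multi_snp": {tp: sorted(s) for tp, s in cds.multi_snp.items()},
        "provenance": {p: cds.provenance(p) for p in sorted(cds.longitudinal)},
    }
    (stage_dir / "cross_dependent.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(
        stage_dir,
        "discover",
        {"alpha": config.alpha, "fit_null": config.fit_null},
        [Path(config.outdir) / "simulate" / tp / "genotypes.vcf" for tp in TIMEPOINTS],
        config.seed,
    )


def _stage_mqtl(config, stage_dir, state):
    spec = VariantFilterSpec(window=config.mqtl_window)
    for tp in TIMEPOINTS:
        genotypes = state[("genotypes", tp)]
        m = state[("m", tp)]
        cov = state[("cov", tp)][["sex", "age", "bmi", "batch"]]
        keep, report = filter_variants(genotypes.meta, spec)
        shared = [s for s in m.sample_ids if s in genotypes.calls.index]
        records = scan_additive(
            genotypes, m.subset(samples=shared), cov.loc[shared], variant_ids=keep
        )
        tp_dir = stage_dir / tp
        tp_dir.mkdir(exist_ok=True)
        records.to_csv(tp_dir / "mqtl.tsv", sep="\t", index=False)
        (tp_dir / "variant_filter_report.json").write_text(json.dumps(report, indent=2))
        ann = state[("ann", tp)]
        probe_pos = ann.loc[[p for p in m.probe_ids if p in ann.index], "pos"]
        mats = heatmap_export(records, genotypes.meta.loc[keep, "pos"], probe_pos)
        for name, df in mats.items():
            df.to_csv(tp_dir / f"heatmap_{name}.tsv", sep="\t")
        crossdep = state.get("crossdep")
        if crossdep and crossdep.longitudinal:
            ranks = {}
            for probe in sorted(crossdep.longitudinal):
                top, placement = rank_partners(
                    records, probe, k=10, named_partners=list(genotypes.variant_ids)
                )
                top.to_csv(tp_dir / f"rank_{probe}.tsv", sep="\t", index=False)
                ranks[probe] = placement
            (tp_dir / "placements.json").write_text(json.dumps(ranks, indent=2))
        state[("mqtl", tp)] = records
    _write_manifest(stage_dir, "mqtl", dataclasses.asdict(spec), [], config.seed)


def _stage_phenotype(config, stage_dir, state):
    for tp in TIMEPOINTS:
        sim_dir = Path(config.outdir) / "simulate" / tp
        pheno = sio.read_sample_table(sim_dir / "phenotype.tsv")["phenotype"]
        m = state[("m", tp)]
        cov = state[("cov", tp)]
        targets = sorted(state.get("crossdep").longitudinal) if state.get("crossdep") else []
        if not targets:
            targets = m.probe_ids[:1]
        tp_dir = stage_dir / tp
        tp_dir.mkdir(exist_ok=True)
        rows = []
        for probe in targets:
            design = pd.DataFrame(
                {
                    "methylation_m": m.values.loc[probe],
                    "sex": cov["sex"],
                    "age": cov["age"],
                    "bmi": cov["bmi"],
                    "batch": cov["batch"],
                }
            )
            fit = fit_logistic(pheno.loc[design.index], design)
            tab = fit.table.copy()
            tab.insert(0, "probe", probe)
            rows.append(tab)
        result = pd.concat(rows)
        result.index.name = "coefficient"
        result.to_csv(tp_dir / "logistic_models.tsv", sep="\t")
        state[("phenotype", tp)] = result
    _write_manifest(stage_dir, "phenotype", {}, [], config.seed)


def _stage_report(config, stage_dir, state):
    cds = state.get("crossdep")
    report = {
        "seed": config.seed,
        "alpha": config.alpha,
        "cross_dependent": {
            "longitudinal": sorted(cds.longitudinal) if cds else [],
            "provenance": {p: cds.provenance(p) for p in sorted(cds.longitudinal)}
            if cds
            else {},
        },
        "phenotype_models": {
            tp: state[("phenotype", tp)].reset_index().to_dict(orient="records")
            for tp in TIMEPOINTS
            if ("phenotype", tp) in state
        },
    }
    (stage_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_manifest(stage_dir, "report", {}, [], config.seed)


_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "discover": _stage_discover,
    "mqtl": _stage_mqtl,
    "phenotype": _stage_phenotype,
    "report": _stage_report,
}
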