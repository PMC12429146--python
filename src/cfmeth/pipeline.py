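"""End-to-end orchestration: simulate -> regions -> DMRs -> signature -> EMT.

A single YAML config drives the run; every stage writes its interchange
file into the output directory so any stage can be re-run from disk alone.
Identical configs and inputs reproduce byte-identical tables.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .core import SampleMethylome
from .dmr import DMRCriteria, DMRecord, call_dmrs
from .emt import EMTGeneSets, gene_beta_matrix, score_cohort
from .enrich import hypergeom_enrichment
from .regions import MeanShiftParams, MethylRegion, call_regions, region_summary
from .signature import (
    build_matrix,
    map_to_signature,
    pick_informative_pc,
    run_pca,
    select_top_loadings,
)
from .simulate import SimConfig, SimTruth, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "regions_from_bed"]

logger = logging.getLogger("cfmeth.pipeline")


@dataclass
class PipelineConfig:
    out_dir: str = "cfmeth_run"
    sample_sheet: str | None = None  # not needed when simulate is set
    genes: str | None = None
    emt_gmt: str | None = None
    simulate: dict | None = None  # SimConfig overrides; triggers generation
    mean_shift: dict = field(default_factory=dict)
    dmr: dict = field(default_factory=dict)
    signature_fraction: float = 0.025
    min_coverage: int = 1
    emt_normalize: str = "rank_uniform"
    case_group: str = "cancer"
    control_group: str = "normal"
    enrich_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def dump(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def validate(self) -> None:
        """Check referenced paths before any compute."""
        if self.simulate is None:
            for name in ("sample_sheet", "genes", "emt_gmt"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config missing required path: {name}")
                if not os.path.exists(p):
                    raise ValueError(f"config path does not exist: {name}={p}")
        params = self.mean_shift_params()  # raises on bad values
        _ = params
        _ = self.dmr_criteria()
        if not (0 < self.signature_fraction < 1):
            raise ValueError("signature_fraction must be in (0, 1)")

    def mean_shift_params(self) -> MeanShiftParams:
        return MeanShiftParams(**self.mean_shift)

    def dmr_criteria(self) -> DMRCriteria:
        return DMRCriteria(**self.dmr)

    def sim_config(self) -> SimConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        return SimConfig(**overrides)


def regions_from_bed(
    bed: pd.DataFrame, samples: list[SampleMethylome]
) -> list[MethylRegion]:
    """Rebuild MethylRegions from a regions BED plus the cohort's CpG calls.

    Member CpGs are the cohort-universe positions inside each [start, end);
    per-sample counts are pooled from the samples. Lets the DMR stage run
    from on-disk inputs alone.
    """
    from .regions import _cohort_arrays

    arrays = _cohort_arrays(samples)
    sample_ids = [s.sample_id for s in samples]
    regions: list[MethylRegion] = []
    for row in bed.itertuples(index=False):
        if row.chrom not in arrays:
            continue
        union, meth, total = arrays[row.chrom]
        lo = np.searchsorted(union, row.start, side="left")
        hi = np.searchsorted(union, row.end, side="left")
        pos = union[lo:hi]
        if pos.size == 0:
            continue
        counts = {
            sid: (int(meth[i, lo:hi].sum()), int(total[i, lo:hi].sum()))
            for i, sid in enumerate(sample_ids)
        }
        regions.append(
            MethylRegion(
                region_id=row.region_id,
                chrom=row.chrom,
                start=int(pos[0]),
                end=int(pos[-1]) + 1,
                cpg_positions=pos.copy(),
                mode=float(pos.mean()),
                per_sample_counts=counts,
            )
        )
    return regions


def _write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="region_id")


def _write_enrichment(results, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "set_name\tn_query\tn_set\tn_overlap\tn_universe\tp_value\tq_value\n"
        )
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.n_query}\t{r.n_set}\t{r.n_overlap}\t"
                f"{r.n_universe}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )


def _truth_report(truth: SimTruth, dmrs: list[DMRecord]) -> dict:
    """Recovery of planted DMRs by the called set (interval overlap)."""
    planted = truth.planted_dmrs
    emt_islands = [i for i in truth.islands if i.role in ("e_gene", "m_gene")]
    null_islands = [i for i in truth.islands if i.role == "null"]

    def overlaps(isl, d):
        return d.region.chrom == truth.chrom and not (
            d.region.end <= isl.start or d.region.start >= isl.end
        )

    recovered = sum(1 for isl in planted if any(overlaps(isl, d) for d in dmrs))
    differential = planted + emt_islands
    false_calls = sum(
        1 for d in dmrs if not any(overlaps(isl, d) for isl in differential)
    )
    return {
        "n_planted_dmrs": len(planted),
        "n_recovered": recovered,
        "recall": recovered / len(planted) if planted else float("nan"),
        "n_called": len(dmrs),
        "n_false_calls": false_calls,
        "n_null_islands": len(null_islands),
        "false_call_rate_per_1000_null": (
            1000.0 * false_calls / len(null_islands) if null_islands else 0.0
        ),
    }


def run_pipeline(config: PipelineConfig) -> str:
    """Run every stage in order; returns the output directory.

    Any stage failure raises with the stage name prepended.
    """
    config.validate()
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(
        logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s %(message)s",
            datefmt="%Y-%m-%dT%H:%M:%S%z",
        )
    )
    root = logging.getLogger("cfmeth")
    root.setLevel(config.log_level)
    root.addHandler(handler)
    stderr = logging.StreamHandler(sys.stderr)
    root.addHandler(stderr)
    try:
        return _run_stages(config, out_dir)
    finally:
        root.removeHandler(handler)
        root.removeHandler(stderr)
        handler.close()


def _run_stages(config: PipelineConfig, out_dir: str) -> str:
    logger.info("config:\n%s", config.dump())
    truth = None
    stage = "simulate"
    try:
        if config.simulate is not None:
            data_dir = os.path.join(out_dir, "data")
            _, truth, paths = simulate_cohort(config.sim_config(), data_dir)
            config.sample_sheet = paths["sample_sheet"]
            config.genes = paths["genes"]
            config.emt_gmt = paths["emt_gmt"]
            logger.info("simulate: wrote cohort to %s", data_dir)

        stage = "load"
        samples = mio.load_cohort(config.sample_sheet)
        gene_models = mio.read_gene_models(config.genes)
        gmt = mio.read_gmt(config.emt_gmt)
        emt_sets = EMTGeneSets.from_collection(gmt)

        stage = "call-regions"
        regions, report = call_regions(samples, config.mean_shift_params())
        mio.write_regions_bed(regions, os.path.join(out_dir, "regions.bed"))
        summary = region_summary(regions)
        logger.info("call-regions: %s (dropped %d)", summary, report["n_dropped"])

        stage = "call-dmrs"
        dmrs = call_dmrs(
            regions,
            samples,
            config.dmr_criteria(),
            gene_models=gene_models,
            case_group=config.case_group,
            control_group=config.control_group,
        )
        mio.write_dmrs_tsv(dmrs, os.path.join(out_dir, "dmrs.tsv"))
        logger.info("call-dmrs: %d DMRs", len(dmrs))

        stage = "select-signature"
        matrix = build_matrix(regions, samples, min_coverage=config.min_coverage)
        _write_matrix(matrix.values, os.path.join(out_dir, "matrix.tsv"))
        pca = run_pca(matrix)
        groups = [s.group for s in samples]
        pc, p = pick_informative_pc(pca, groups)
        selected, cutoff = select_top_loadings(pca, pc, config.signature_fraction)
        selection = map_to_signature(
            selected, regions, gene_models, emt_sets, pc, p, cutoff
        )
        with open(os.path.join(out_dir, "signature.json"), "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(selection), fh, indent=1, sort_keys=True)
            fh.write("\n")
        logger.info(
            "select-signature: PC%d (p=%.3g), %d regions, %d genes",
            pc + 1, p, len(selection.selected_regions), len(selection.selected_genes),
        )

        stage = "emt-score"
        gene_betas = gene_beta_matrix(regions, gene_models)
        scores = score_cohort(gene_betas, emt_sets, normalize=config.emt_normalize)
        group_of = {s.sample_id: s.group for s in samples}
        mio.write_scores_tsv(scores, os.path.join(out_dir, "scores.tsv"), group_of)
        logger.info("emt-score: %d samples scored", len(scores))

        stage = "enrich"
        universe = set(gene_betas.index)
        dmg = sorted({d.gene_id for d in dmrs if d.gene_id} & universe)
        results = hypergeom_enrichment(dmg, gmt, universe)
        _write_enrichment(results, os.path.join(out_dir, "enrichment.tsv"))
        logger.info("enrich: %d sets tested against %d DMGs", len(results), len(dmg))

        if truth is not None:
            stage = "truth-report"
            report = _truth_report(truth, dmrs)
            with open(os.path.join(out_dir, "truth_report.json"), "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=1, sort_keys=True)
                fh.write("\n")
            logger.info("truth-report: %s", report)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out_dir
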