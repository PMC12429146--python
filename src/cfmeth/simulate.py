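"""Synthetic cfBS cohort generator with planted ground truth.

One synthetic chromosome carries CpG islands (clustered CpG runs whose
terminal CpGs define the island span), sparse background CpGs between them,
and three kinds of planted biology:

* DMR islands — the case ("cancer") group mean beta is shifted by a
  configurable delta (random sign) from the control ("normal") baseline;
* an epithelial/mesenchymal methylation axis — islands in the promoter
  window of planted E genes are hypermethylated in the case group and
  M-gene islands hypomethylated, so case samples score mesenchymal;
* null islands — one shared group mean.

Per sample, each island draws its own beta from a Beta distribution centred
on the group mean (beta-binomial replicate variance), coverage per CpG is
Poisson, and methylated counts are binomial. The generator emits data files
in the formats the pipeline consumes plus a ground-truth record for
recovery tests.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneModel, SampleMethylome
from .emt import EMTGeneSets
from . import io as mio

__all__ = [
    "EMTAxis",
    "SimConfig",
    "Island",
    "SimTruth",
    "simulate_layout",
    "simulate_sample",
    "simulate_cohort",
    "simulate_region_matrix",
    "simulate_stage_betas",
]


@dataclass(frozen=True)
class EMTAxis:
    """Group-mean beta for planted epithelial and mesenchymal gene islands.

    Defaults encode promoter hypermethylation of epithelial genes and
    hypomethylation of mesenchymal genes in the case group.
    """

    e_mean_normal: float = 0.30
    e_mean_cancer: float = 0.50
    m_mean_normal: float = 0.60
    m_mean_cancer: float = 0.30


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 4 control vs 3 case samples at a
    mean per-CpG depth of 25x (within the reported 20-35x range), islands
    averaging 250 bp and 10 CpGs, at least 2 kb apart.
    """

    seed: int = 0
    n_normal: int = 4
    n_cancer: int = 3
    n_islands: int = 1200
    island_span_mean: float = 250.0
    island_span_sd: float = 30.0
    cpgs_per_island_mean: float = 10.0
    island_max_gap_bp: int = 80  # islands are dense: cap intra-island CpG spacing
    inter_island_gap_bp: int = 2000
    background_cpg_per_kb: float = 0.5
    depth_mean: float = 25.0
    dmr_fraction: float = 0.2
    dmr_delta: float = 0.3
    beta_concentration: float = 200.0
    baseline_beta_range: tuple[float, float] = (0.35, 0.65)
    background_beta: float = 0.75
    n_e_genes: int = 30
    n_m_genes: int = 15
    emt_axis: EMTAxis = field(default_factory=EMTAxis)
    gene_fraction: float = 0.5  # null islands additionally assigned a gene
    chrom: str = "chrS"
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_cancer, self.n_islands) <= 0:
            raise ValueError("sample and island counts must be > 0")
        if not (0 < self.dmr_delta < 1):
            raise ValueError("dmr_delta must be in (0, 1)")
        if not (0 <= self.dmr_fraction <= 1):
            raise ValueError("dmr_fraction must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        n_special = round(self.dmr_fraction * self.n_islands)
        n_special += self.n_e_genes + self.n_m_genes
        if n_special > self.n_islands:
            raise ValueError(
                "dmr_fraction plus E/M gene islands exceed n_islands"
            )


@dataclass
class Island:
    index: int
    start: int
    end: int  # half-open; start/end - 1 are the terminal CpGs
    cpg_positions: np.ndarray
    role: str  # null | dmr | e_gene | m_gene
    mean_normal: float
    mean_cancer: float
    gene_id: str | None = None
    dmr_sign: int | None = None

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)


@dataclass
class SimTruth:
    """Planted layout and effects, the oracle for recovery tests."""

    chrom: str
    chrom_length: int
    islands: list[Island]
    gene_models: list[GeneModel]
    e_genes: frozenset[str]
    m_genes: frozenset[str]
    background_positions: np.ndarray
    background_beta: float

    @property
    def planted_dmrs(self) -> list[Island]:
        return [i for i in self.islands if i.role == "dmr"]

    def emt_sets(self) -> EMTGeneSets:
        return EMTGeneSets(self.e_genes, self.m_genes)

    def position_arrays(self):
        """(positions, mean_normal, mean_cancer, island_index) over all CpGs.

        island_index is -1 for background CpGs. Cached after first call.
        """
        cached = getattr(self, "_pos_arrays", None)
        if cached is not None:
            return cached
        pos_parts = [isl.cpg_positions for isl in self.islands]
        pos_parts.append(self.background_positions)
        positions = np.concatenate(pos_parts)
        mn = np.concatenate(
            [
                np.full(isl.n_cpg, isl.mean_normal)
                for isl in self.islands
            ]
            + [np.full(len(self.background_positions), self.background_beta)]
        )
        mc = np.concatenate(
            [
                np.full(isl.n_cpg, isl.mean_cancer)
                for isl in self.islands
            ]
            + [np.full(len(self.background_positions), self.background_beta)]
        )
        idx = np.concatenate(
            [np.full(isl.n_cpg, isl.index) for isl in self.islands]
            + [np.full(len(self.background_positions), -1)]
        )
        order = np.argsort(positions, kind="stable")
        self._pos_arrays = (
            positions[order],
            mn[order],
            mc[order],
            idx[order],
        )
        return self._pos_arrays

    def to_json(self, path) -> None:
        payload = {
            "chrom": self.chrom,
            "chrom_length": self.chrom_length,
            "background_beta": self.background_beta,
            "background_positions": self.background_positions.tolist(),
            "e_genes": sorted(self.e_genes),
            "m_genes": sorted(self.m_genes),
            "genes": [
                dataclasses.asdict(g) for g in self.gene_models
            ],
            "islands": [
                {
                    "index": i.index,
                    "start": i.start,
                    "end": i.end,
                    "cpg_positions": i.cpg_positions.tolist(),
                    "role": i.role,
                    "mean_normal": i.mean_normal,
                    "mean_cancer": i.mean_cancer,
                    "gene_id": i.gene_id,
                    "dmr_sign": i.dmr_sign,
                }
                for i in self.islands
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        islands = [
            Island(
                index=d["index"],
                start=d["start"],
                end=d["end"],
                cpg_positions=np.asarray(d["cpg_positions"], dtype=np.int64),
                role=d["role"],
                mean_normal=d["mean_normal"],
                mean_cancer=d["mean_cancer"],
                gene_id=d["gene_id"],
                dmr_sign=d["dmr_sign"],
            )
            for d in payload["islands"]
        ]
        genes = [GeneModel(**g) for g in payload["genes"]]
        return cls(
            chrom=payload["chrom"],
            chrom_length=payload["chrom_length"],
            islands=islands,
            gene_models=genes,
            e_genes=frozenset(payload["e_genes"]),
            m_genes=frozenset(payload["m_genes"]),
            background_positions=np.asarray(
                payload["background_positions"], dtype=np.int64
            ),
            background_beta=payload["background_beta"],
        )


def simulate_layout(config: SimConfig) -> SimTruth:
    """Place islands, assign roles/effects/genes, scatter background CpGs.

    Deterministic in config.seed. Raises when a fixed chrom_length cannot
    hold the islands with the configured minimum gaps.
    """
    rng = np.random.default_rng(config.seed)
    density = config.cpgs_per_island_mean / config.island_span_mean
    cursor = 1000
    geoms: list[tuple[int, int, np.ndarray]] = []
    for _ in range(config.n_islands):
        span = int(
            max(100, round(rng.normal(config.island_span_mean, config.island_span_sd)))
        )
        # CpG count tracks span so island density stays roughly constant;
        # the floor keeps the max-gap cap attainable
        floor = max(3, int(np.ceil((span - 1) / config.island_max_gap_bp)) + 1)
        ncpg = int(max(floor, rng.poisson(span * density)))
        ncpg = min(ncpg, span)
        start, end = cursor, cursor + span
        if config.chrom_length is not None and end > config.chrom_length:
            raise ValueError(
                f"cannot place {config.n_islands} islands within "
                f"chrom_length={config.chrom_length}"
            )
        # terminal CpGs sit at the span edges so hull length == span;
        # interior positions are uniform without replacement, redrawn until
        # no intra-island gap exceeds the cap (islands are dense)
        for _attempt in range(500):
            interior = (
                np.sort(rng.choice(span - 2, size=ncpg - 2, replace=False)) + 1
                if ncpg > 2
                else np.empty(0, dtype=np.int64)
            )
            offsets = np.concatenate(([0], interior, [span - 1]))
            if np.diff(offsets).max() <= config.island_max_gap_bp:
                break
        positions = (offsets + start).astype(np.int64)
        geoms.append((start, end, positions))
        cursor = end + config.inter_island_gap_bp + int(rng.exponential(500.0))
    chrom_length = (
        config.chrom_length if config.chrom_length is not None else cursor + 1000
    )

    n_dmr = round(config.dmr_fraction * config.n_islands)
    perm = rng.permutation(config.n_islands)
    dmr_set = set(perm[:n_dmr].tolist())
    e_set = set(perm[n_dmr : n_dmr + config.n_e_genes].tolist())
    m_set = set(
        perm[
            n_dmr + config.n_e_genes : n_dmr + config.n_e_genes + config.n_m_genes
        ].tolist()
    )
    lo, hi = config.baseline_beta_range
    baselines = rng.uniform(lo, hi, size=config.n_islands)
    dmr_signs = rng.choice(np.array([-1, 1]), size=config.n_islands)
    gene_lottery = rng.uniform(size=config.n_islands)

    islands: list[Island] = []
    gene_models: list[GeneModel] = []
    e_genes: set[str] = set()
    m_genes: set[str] = set()
    ax = config.emt_axis
    e_counter = m_counter = 0
    for i, (start, end, positions) in enumerate(geoms):
        if i in dmr_set:
            role = "dmr"
            sign = int(dmr_signs[i])
            mn = float(baselines[i])
            mc = float(np.clip(mn + sign * config.dmr_delta, 0.02, 0.98))
            gene_id = f"GENE{i + 1:05d}"
        elif i in e_set:
            role, sign = "e_gene", None
            mn, mc = ax.e_mean_normal, ax.e_mean_cancer
            e_counter += 1
            gene_id = f"EPI{e_counter:04d}"
            e_genes.add(gene_id)
        elif i in m_set:
            role, sign = "m_gene", None
            mn, mc = ax.m_mean_normal, ax.m_mean_cancer
            m_counter += 1
            gene_id = f"MES{m_counter:04d}"
            m_genes.add(gene_id)
        else:
            role, sign = "null", None
            mn = mc = float(baselines[i])
            gene_id = (
                f"GENE{i + 1:05d}" if gene_lottery[i] < config.gene_fraction else None
            )
        islands.append(
            Island(
                index=i,
                start=start,
                end=end,
                cpg_positions=positions,
                role=role,
                mean_normal=mn,
                mean_cancer=mc,
                gene_id=gene_id,
                dmr_sign=sign,
            )
        )
        if gene_id is not None:
            gene_models.append(_gene_for_island(config.chrom, i, start, end, gene_id))

    background = _background_positions(rng, config, geoms, chrom_length)
    return SimTruth(
        chrom=config.chrom,
        chrom_length=chrom_length,
        islands=islands,
        gene_models=gene_models,
        e_genes=frozenset(e_genes),
        m_genes=frozenset(m_genes),
        background_positions=background,
        background_beta=config.background_beta,
    )


def _gene_for_island(chrom, index, start, end, gene_id) -> GeneModel:
    """A 1 kb gene whose promoter window covers the island.

    Strand alternates with island parity; the minus-strand layout falls back
    to plus when it would run off the chromosome start.
    """
    if index % 2 == 1 and start - 1500 >= 0:
        g_end = start - 500
        return GeneModel(gene_id, chrom, g_end - 1000, g_end, "-")
    g_start = end + 500
    return GeneModel(gene_id, chrom, g_start, g_start + 1000, "+")


def _background_positions(rng, config, geoms, chrom_length) -> np.ndarray:
    """Sparse background CpGs uniform over the inter-island gaps."""
    gaps: list[tuple[int, int]] = []
    prev_end = 0
    for start, end, _ in geoms:
        if start > prev_end:
            gaps.append((prev_end, start))
        prev_end = end
    if chrom_length > prev_end:
        gaps.append((prev_end, chrom_length))
    total = sum(e - s for s, e in gaps)
    n_bg = int(rng.poisson(config.background_cpg_per_kb * total / 1000.0))
    if n_bg == 0 or total == 0:
        return np.empty(0, dtype=np.int64)
    offsets = np.sort(rng.choice(total, size=min(n_bg, total), replace=False))
    widths = np.array([e - s for s, e in gaps])
    starts = np.array([s for s, _ in gaps])
    cum = np.concatenate(([0], np.cumsum(widths)))
    gap_idx = np.searchsorted(cum, offsets, side="right") - 1
    return (starts[gap_idx] + (offsets - cum[gap_idx])).astype(np.int64)


def _draw_betas(rng, means, concentration) -> np.ndarray:
    """Beta-distributed betas centred on ``means``; degenerate means and an
    infinite concentration collapse to the mean itself."""
    means = np.asarray(means, dtype=float)
    out = means.copy()
    if not np.isfinite(concentration):
        return out
    interior = (means > 0) & (means < 1)
    a = means[interior] * concentration
    b = (1 - means[interior]) * concentration
    out[interior] = rng.beta(a, b)
    return out


def simulate_sample(
    truth: SimTruth,
    config: SimConfig,
    group: str,
    sample_id: str = "sample",
    stage: str | None = None,
    rng: np.random.Generator | None = None,
) -> SampleMethylome:
    """Draw one sample: per-island beta, Poisson coverage, binomial counts.

    Zero-coverage CpGs are kept with n_total = 0.
    """
    if group not in ("normal", "cancer"):
        raise ValueError("group must be 'normal' or 'cancer'")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    positions, mn, mc, island_idx = truth.position_arrays()
    means = mc if group == "cancer" else mn
    # one beta per island per sample; background CpGs draw independently
    beta = np.empty(positions.size, dtype=float)
    for isl in truth.islands:
        member = island_idx == isl.index
        m = means[member]
        beta[member] = _draw_betas(rng, m[:1], config.beta_concentration)[0]
    bg = island_idx == -1
    beta[bg] = _draw_betas(rng, means[bg], config.beta_concentration)
    n_total = rng.poisson(config.depth_mean, size=positions.size)
    n_meth = rng.binomial(n_total, beta)
    df = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": positions.astype(np.int64),
            "n_meth": n_meth.astype(np.int64),
            "n_total": n_total.astype(np.int64),
        }
    )
    return SampleMethylome(sample_id, group, df, stage=stage)


def simulate_cohort(config: SimConfig, out_dir: str | os.PathLike | None = None):
    """Simulate the full cohort; optionally write the pipeline's input files.

    Returns (samples, truth, paths) where paths maps logical names to files
    (None when out_dir is None). Identical configs produce byte-identical
    files.
    """
    truth = simulate_layout(config)
    names = [(f"normal_{i + 1}", "normal") for i in range(config.n_normal)]
    names += [(f"cancer_{i + 1}", "cancer") for i in range(config.n_cancer)]
    seeds = np.random.SeedSequence([config.seed, 7]).spawn(len(names))
    samples = [
        simulate_sample(
            truth, config, group, sample_id=sid, rng=np.random.default_rng(ss)
        )
        for (sid, group), ss in zip(names, seeds)
    ]
    paths = None
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for s in samples:
            p = os.path.join(out_dir, f"{s.sample_id}.bedGraph")
            mio.write_bedgraph(s, p)
            paths[s.sample_id] = p
        genes_path = os.path.join(out_dir, "genes.bed")
        with open(genes_path, "w", encoding="utf-8") as fh:
            for g in truth.gene_models:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        paths["genes"] = genes_path
        gmt_path = os.path.join(out_dir, "emt.gmt")
        with open(gmt_path, "w", encoding="utf-8") as fh:
            fh.write("EPI\tplanted epithelial genes\t" + "\t".join(sorted(truth.e_genes)) + "\n")
            fh.write("MES\tplanted mesenchymal genes\t" + "\t".join(sorted(truth.m_genes)) + "\n")
        paths["emt_gmt"] = gmt_path
        sheet_path = os.path.join(out_dir, "samples.tsv")
        with open(sheet_path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tgroup\tstage\tpath\n")
            for s in samples:
                fh.write(
                    f"{s.sample_id}\t{s.group}\tNA\t{s.sample_id}.bedGraph\n"
                )
        paths["sample_sheet"] = sheet_path
        truth_path = os.path.join(out_dir, "truth.json")
        truth.to_json(truth_path)
        paths["truth"] = truth_path
    return samples, truth, paths


# ---------------------------------------------------------------------------
# matrix-level generators for the PCA and EMT stages


def simulate_region_matrix(
    seed,
    n_regions: int = 1000,
    n_signal: int = 25,
    n_control: int = 4,
    n_case: int = 3,
    delta: float = 0.3,
    concentration: float = 200.0,
    baseline_range: tuple[float, float] = (0.35, 0.65),
):
    """Region x sample beta matrix with a planted group shift on a subset.

    Returns (DataFrame, group labels, signal region ids). Signal regions
    shift the case group mean by +/- delta (random sign per region).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = baseline_range
    baselines = rng.uniform(lo, hi, size=n_regions)
    signal_idx = np.sort(rng.choice(n_regions, size=n_signal, replace=False))
    signs = rng.choice(np.array([-1.0, 1.0]), size=n_signal)
    case_means = baselines.copy()
    case_means[signal_idx] = np.clip(
        baselines[signal_idx] + signs * delta, 0.02, 0.98
    )
    sample_ids = [f"normal_{i + 1}" for i in range(n_control)]
    sample_ids += [f"cancer_{i + 1}" for i in range(n_case)]
    groups = ["normal"] * n_control + ["cancer"] * n_case
    cols = {}
    for sid, grp in zip(sample_ids, groups):
        means = case_means if grp == "cancer" else baselines
        cols[sid] = _draw_betas(rng, means, concentration)
    region_ids = [f"region_{i + 1:06d}" for i in range(n_regions)]
    df = pd.DataFrame(cols, index=region_ids)
    return df, groups, [region_ids[i] for i in signal_idx]


def simulate_stage_betas(
    seed,
    n_per_stage: int = 200,
    stages: tuple[str, ...] = ("I", "II", "III", "IV"),
    n_e: int = 40,
    n_m: int = 20,
    e_mean: float = 0.40,
    m_means: tuple[float, ...] = (0.55, 0.45, 0.35, 0.25),
    concentration: float = 50.0,
):
    """Gene x sample beta matrix with a stage-increasing mesenchymal shift.

    M-gene methylation decreases with stage while E genes stay flat, so the
    mesenchymal fraction (EMT score > 0) rises along stages. Returns
    (DataFrame, stage labels, EMTGeneSets).
    """
    if len(m_means) != len(stages):
        raise ValueError("m_means must match stages")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_genes = [f"EPI{i + 1:04d}" for i in range(n_e)]
    m_genes = [f"MES{i + 1:04d}" for i in range(n_m)]
    cols, labels = {}, []
    k = 0
    for stage, m_mean in zip(stages, m_means):
        for _ in range(n_per_stage):
            k += 1
            sid = f"tumor_{k:04d}"
            e_vals = _draw_betas(rng, np.full(n_e, e_mean), concentration)
            m_vals = _draw_betas(rng, np.full(n_m, m_mean), concentration)
            cols[sid] = np.concatenate((e_vals, m_vals))
            labels.append(stage)
    df = pd.DataFrame(cols, index=e_genes + m_genes)
    return df, labels, EMTGeneSets(frozenset(e_genes), frozenset(m_genes))
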