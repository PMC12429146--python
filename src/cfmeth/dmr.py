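"""Differential methylation testing per region.

Reads are pooled across samples within each group into a 2x2 table
(group x methylated/unmethylated) and tested with a two-sided Fisher exact
test; the effect size is the difference of group means of per-sample pooled
methylation ratios (case minus control). A region is called a DMR when the
p-value clears ``p_max`` and the absolute difference clears ``min_abs_diff``
after a per-CpG coverage filter. Called DMRs are annotated to promoters
(a fixed window upstream of the TSS), gene bodies, or intergenic space.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .core import GeneModel, SampleMethylome
from .regions import MethylRegion, _cohort_arrays

__all__ = [
    "DMRCriteria",
    "DMRecord",
    "fisher_exact_two_sided",
    "coverage_filter",
    "mean_diff",
    "call_dmrs",
    "GeneIndex",
    "annotate_dmr",
    "overlap_test",
]

logger = logging.getLogger(__name__)

PROMOTER_BP = 5000  # promoter = this many bp upstream of the TSS

_REL_TOL = 1e-7  # relative tolerance on the <= comparison of point probabilities


@dataclass(frozen=True)
class DMRCriteria:
    """DMR thresholds.

    p_max
        Raw two-sided Fisher p must be below this (no FDR at this stage).
    min_abs_diff
        |case mean beta - control mean beta| must reach this (fraction,
        0.10 == 10 percentage points).
    coverage_multiplier
        A CpG is kept when its read total reaches coverage_multiplier x n,
        the "2n" rule; n is the cohort size under scope="cohort" or each
        group's size under scope="per_group".
    min_cpg
        Regions with fewer surviving CpGs after the coverage filter are
        discarded.
    """

    p_max: float = 1e-8
    min_abs_diff: float = 0.10
    coverage_multiplier: float = 2.0
    coverage_scope: str = "cohort"
    min_cpg: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")
        if not (0 <= self.min_abs_diff < 1):
            raise ValueError("min_abs_diff must be in [0, 1)")
        if self.coverage_scope not in ("cohort", "per_group"):
            raise ValueError("coverage_scope must be 'cohort' or 'per_group'")


@dataclass
class DMRecord:
    """A differentially methylated region with test results and annotation."""

    region: MethylRegion
    table: np.ndarray  # rows case/control, cols methylated/unmethylated
    p_value: float
    mean_diff: float
    direction: str  # hyper / hypo (case relative to control)
    annotation: str = "intergenic"
    gene_id: str = ""
    tss_distance: float | None = None
    q_value: float | None = None  # BH over all tested regions, informational


# ---------------------------------------------------------------------------
# Fisher's exact test


def _fisher_two_sided_support(r1: int, r2: int, c1: int):
    """Two-sided Fisher p for every table in a margin class.

    For fixed margins (row sums r1, r2; first column sum c1) return
    ``(support, p)`` where support enumerates the top-left cell and p[k] is
    the two-sided p of that table: the sum of hypergeometric point
    probabilities <= the observed one (relative tolerance on the comparison).
    """
    N = r1 + r2
    if N == 0:
        return np.array([0]), np.array([1.0])
    kmin = max(0, c1 - r2)
    kmax = min(c1, r1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1 + _REL_TOL), side="right")
    p = np.minimum(cum[idx - 1], 1.0)
    return support, p


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    p is the sum of hypergeometric point probabilities not exceeding the
    observed table's probability; p = 1 whenever a margin is zero.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    support, p = _fisher_two_sided_support(r1, r2, c1)
    return float(p[a - support[0]])


# ---------------------------------------------------------------------------
# coverage filter and effect size


def coverage_filter(
    region: MethylRegion,
    samples: list[SampleMethylome],
    criteria: DMRCriteria,
) -> MethylRegion | None:
    """Drop under-covered CpGs from a region; None if too few survive.

    A CpG survives when its read total summed across all samples reaches
    ``coverage_multiplier x n_samples`` (or, under scope="per_group", the
    within-group total reaches ``coverage_multiplier x group size`` in every
    group). Pooled per-sample counts are recomputed from surviving CpGs.
    """
    arrays = _cohort_arrays(samples)
    union, meth, total = arrays[region.chrom]
    idx = np.searchsorted(union, region.cpg_positions)
    groups = [s.group for s in samples]
    keep = _coverage_mask(total[:, idx], groups, criteria)
    return _rebuild_region(region, idx, keep, meth, total, [s.sample_id for s in samples], criteria)


def _coverage_mask(totals: np.ndarray, groups: list[str], criteria: DMRCriteria):
    """Boolean keep-mask over CpG columns of a (samples x cpgs) total matrix."""
    if criteria.coverage_scope == "cohort":
        thresh = criteria.coverage_multiplier * len(groups)
        return totals.sum(axis=0) >= thresh
    keep = np.ones(totals.shape[1], dtype=bool)
    garr = np.asarray(groups)
    for g in np.unique(garr):
        member = garr == g
        keep &= totals[member].sum(axis=0) >= criteria.coverage_multiplier * member.sum()
    return keep


def _rebuild_region(region, idx, keep, meth, total, sample_ids, criteria):
    if keep.sum() < criteria.min_cpg:
        return None
    kept_idx = idx[keep]
    pos = region.cpg_positions[keep]
    counts = {
        sid: (int(meth[i, kept_idx].sum()), int(total[i, kept_idx].sum()))
        for i, sid in enumerate(sample_ids)
    }
    return MethylRegion(
        region_id=region.region_id,
        chrom=region.chrom,
        start=int(pos[0]),
        end=int(pos[-1]) + 1,
        cpg_positions=pos.copy(),
        mode=region.mode,
        per_sample_counts=counts,
    )


def mean_diff(
    region: MethylRegion,
    samples: list[SampleMethylome],
    case_group: str = "cancer",
    control_group: str = "normal",
) -> float:
    """Case-minus-control difference of group means of per-sample region beta.

    Per-sample beta is the pooled ratio over the region's CpGs; samples with
    zero pooled coverage are excluded from their group's mean. NaN when a
    group has no covered sample.
    """
    betas = region.per_sample_beta
    by_group: dict[str, list[float]] = {case_group: [], control_group: []}
    for s in samples:
        if s.group in by_group:
            b = betas.get(s.sample_id, float("nan"))
            if not np.isnan(b):
                by_group[s.group].append(b)
    if not by_group[case_group] or not by_group[control_group]:
        return float("nan")
    return float(np.mean(by_group[case_group]) - np.mean(by_group[control_group]))


# ---------------------------------------------------------------------------
# genomic annotation


class GeneIndex:
    """Interval lookup of promoter and gene-body windows.

    Promoter: PROMOTER_BP upstream of the TSS, strand-aware. Gene body: the
    TSS-to-TES span. Promoter assignment takes precedence over body; among
    multiple candidates the gene with the nearest TSS wins.
    """

    def __init__(self, gene_models: list[GeneModel], promoter_bp: int = PROMOTER_BP):
        self.promoter_bp = promoter_bp
        self._promoters: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        for g in gene_models:
            if g.strand == "+":
                p_start, p_end = g.start - promoter_bp, g.start
            else:
                p_start, p_end = g.end, g.end + promoter_bp
            if p_end > p_start:
                self._promoters.setdefault(g.chrom, IntervalTree()).addi(
                    p_start, p_end, g
                )
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    @staticmethod
    def tss_distance(gene: GeneModel, midpoint: float) -> float:
        """Signed distance from a point to the TSS; upstream is negative."""
        d = midpoint - gene.tss
        return d if gene.strand == "+" else -d

    def annotate(self, chrom: str, start: int, end: int):
        """Classify an interval: (annotation, gene_id, tss_distance)."""
        mid = (start + end) / 2.0
        for kind, trees in (("promoter", self._promoters), ("gene body", self._bodies)):
            tree = trees.get(chrom)
            if tree is None:
                continue
            hits = [iv.data for iv in tree.overlap(start, end)]
            if hits:
                best = min(
                    hits,
                    key=lambda g: (abs(self.tss_distance(g, mid)), g.gene_id),
                )
                return kind, best.gene_id, self.tss_distance(best, mid)
        return "intergenic", "", None


def annotate_dmr(dmr: DMRecord, gene_models: list[GeneModel] | GeneIndex) -> DMRecord:
    """Fill a DMRecord's annotation, gene and TSS distance in place."""
    index = (
        gene_models
        if isinstance(gene_models, GeneIndex)
        else GeneIndex(gene_models)
    )
    ann, gid, tssd = index.annotate(dmr.region.chrom, dmr.region.start, dmr.region.end)
    dmr.annotation, dmr.gene_id, dmr.tss_distance = ann, gid, tssd
    return dmr


# ---------------------------------------------------------------------------
# DMR calling


def call_dmrs(
    regions: list[MethylRegion],
    samples: list[SampleMethylome],
    criteria: DMRCriteria | None = None,
    gene_models: list[GeneModel] | None = None,
    case_group: str = "cancer",
    control_group: str = "normal",
) -> list[DMRecord]:
    """Test every region and return called DMRs sorted by p ascending.

    Pipeline per region: coverage filter -> pooled 2x2 group table ->
    two-sided Fisher p -> group-mean beta difference -> retain when
    p < p_max and |diff| >= min_abs_diff. A BH-adjusted q over all tested
    regions is attached for information; the call itself uses raw p.
    """
    from .enrich import bh_adjust

    criteria = criteria or DMRCriteria()
    labels = {s.group for s in samples}
    if len(labels) < 2:
        raise ValueError("cohort has a single group; need case and control")
    if case_group not in labels or control_group not in labels:
        raise ValueError(
            f"groups {sorted(labels)} do not include case={case_group!r} "
            f"and control={control_group!r}"
        )
    arrays = _cohort_arrays(samples)
    sample_ids = [s.sample_id for s in samples]
    groups = [s.group for s in samples]
    garr = np.asarray(groups)
    case_rows = np.where(garr == case_group)[0]
    ctrl_rows = np.where(garr == control_group)[0]

    tested: list[DMRecord] = []
    n_cov_dropped = 0
    n_uncovered_group = 0
    for region in regions:
        union, meth, total = arrays[region.chrom]
        idx = np.searchsorted(union, region.cpg_positions)
        keep = _coverage_mask(total[:, idx], groups, criteria)
        filtered = _rebuild_region(
            region, idx, keep, meth, total, sample_ids, criteria
        )
        if filtered is None:
            n_cov_dropped += 1
            continue
        diff = mean_diff(filtered, samples, case_group, control_group)
        if np.isnan(diff):
            n_uncovered_group += 1
            continue
        kept_idx = idx[keep]
        case_meth = int(meth[np.ix_(case_rows, kept_idx)].sum())
        case_total = int(total[np.ix_(case_rows, kept_idx)].sum())
        ctrl_meth = int(meth[np.ix_(ctrl_rows, kept_idx)].sum())
        ctrl_total = int(total[np.ix_(ctrl_rows, kept_idx)].sum())
        table = np.array(
            [
                [case_meth, case_total - case_meth],
                [ctrl_meth, ctrl_total - ctrl_meth],
            ],
            dtype=np.int64,
        )
        p = fisher_exact_two_sided(table)
        direction = "hyper" if diff > 0 else ("hypo" if diff < 0 else "none")
        tested.append(
            DMRecord(
                region=filtered,
                table=table,
                p_value=p,
                mean_diff=diff,
                direction=direction,
            )
        )
    if n_cov_dropped or n_uncovered_group:
        logger.info(
            "call_dmrs: %d regions dropped by coverage filter, "
            "%d with an uncovered group",
            n_cov_dropped,
            n_uncovered_group,
        )
    if tested:
        qs = bh_adjust([d.p_value for d in tested])
        for d, q in zip(tested, qs):
            d.q_value = float(q)
    called = [
        d
        for d in tested
        if d.p_value < criteria.p_max and abs(d.mean_diff) >= criteria.min_abs_diff
    ]
    called.sort(key=lambda d: (d.p_value, d.region.chrom, d.region.start))
    if gene_models is not None:
        index = GeneIndex(gene_models)
        for d in called:
            annotate_dmr(d, index)
    return called


# ---------------------------------------------------------------------------
# gene-overlap significance


def overlap_test(
    n_query: int, n_reference: int, n_overlap: int, n_universe: int
) -> float:
    """Upper-tail hypergeometric p that an overlap this large arises by chance.

    P(X >= n_overlap) with X ~ Hypergeom(n_universe, n_reference, n_query).
    """
    if min(n_query, n_reference, n_overlap, n_universe) < 0:
        raise ValueError("counts must be non-negative")
    if n_overlap > min(n_query, n_reference):
        raise ValueError("n_overlap exceeds min(n_query, n_reference)")
    if max(n_query, n_reference) > n_universe:
        raise ValueError("query/reference larger than the universe")
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_reference, n_query))
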