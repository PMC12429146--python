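"""Mean-shift segmentation of CpG sites into methylation regions.

CpG coordinates on a chromosome are clustered by 1-D mean shift with a flat
(top-hat) kernel: each site is iteratively moved to the mean of all sites
inside a fixed-width window centred on it until the shift falls below a
tolerance. Sites whose converged modes lie close together (single linkage on
sorted modes) form one region. Methylation does not weight the shift; it
enters only through the per-sample read counts pooled over a region's
member CpGs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SampleMethylome

__all__ = [
    "MeanShiftParams",
    "MethylRegion",
    "RegionSummary",
    "mean_shift_modes",
    "cluster_by_mode",
    "build_regions",
    "call_regions",
    "region_summary",
]


@dataclass(frozen=True)
class MeanShiftParams:
    """Tunables of the segmentation.

    bandwidth_bp
        Full width of the flat window (bp). The window stays fixed through
        the iteration.
    shift_tol_bp
        A site stops moving once its update is smaller than this (bp).
    max_iter
        Iteration cap per site.
    merge_dist_bp
        Converged modes within this distance (single linkage) share a
        region. Default is one window width: the modes of a single dense
        CpG island can sit up to roughly a window apart, while distinct
        islands are separated by far more.
    min_cpg
        Regions with fewer member CpGs are dropped (and counted).
    """

    bandwidth_bp: float = 200.0
    shift_tol_bp: float = 0.5
    max_iter: int = 100
    merge_dist_bp: float = 200.0
    min_cpg: int = 3

    def __post_init__(self) -> None:
        if self.bandwidth_bp <= 0:
            raise ValueError("bandwidth_bp must be > 0")
        if self.merge_dist_bp < self.shift_tol_bp:
            raise ValueError("merge_dist_bp must be >= shift_tol_bp")
        if self.max_iter < 1 or self.min_cpg < 1:
            raise ValueError("max_iter and min_cpg must be >= 1")


@dataclass
class MethylRegion:
    """A clustered run of CpG sites with per-sample pooled counts."""

    region_id: str
    chrom: str
    start: int
    end: int  # half-open hull: last CpG position + 1
    cpg_positions: np.ndarray
    mode: float
    per_sample_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def per_sample_beta(self) -> dict[str, float]:
        """Pooled n_meth / n_total per sample; NaN where uncovered."""
        out = {}
        for sid, (m, t) in self.per_sample_counts.items():
            out[sid] = m / t if t > 0 else float("nan")
        return out

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def mean_shift_modes(positions, params: MeanShiftParams) -> np.ndarray:
    """Converged mean-shift mode for each starting position.

    ``positions`` must be sorted ascending within one chromosome. For each
    site, x is replaced by the mean of all sites within bandwidth/2 of x
    until |shift| < shift_tol_bp or max_iter. Deterministic; empty input
    returns an empty array.
    """
    pos = np.asarray(positions, dtype=np.float64)
    if pos.ndim != 1:
        raise ValueError("positions must be 1-D")
    if pos.size == 0:
        return np.empty(0, dtype=np.float64)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    half = params.bandwidth_bp / 2.0
    csum = np.concatenate(([0.0], np.cumsum(pos)))
    x = pos.copy()
    active = np.arange(pos.size)
    for _ in range(params.max_iter):
        if active.size == 0:
            break
        xa = x[active]
        lo = np.searchsorted(pos, xa - half, side="left")
        hi = np.searchsorted(pos, xa + half, side="right")
        # a flat window centred on a mean of in-window points always
        # contains at least one point in 1-D; guard regardless
        n = np.maximum(hi - lo, 1)
        new = (csum[hi] - csum[lo]) / n
        moved = np.abs(new - xa) >= params.shift_tol_bp
        x[active] = new
        active = active[moved]
    return x


def cluster_by_mode(positions, modes, params: MeanShiftParams) -> np.ndarray:
    """Region label per position: single linkage on sorted modes at
    merge_dist_bp. Labels are contiguous integers in genomic order."""
    modes = np.asarray(modes, dtype=np.float64)
    n = modes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(modes, kind="stable")
    sorted_modes = modes[order]
    breaks = np.diff(sorted_modes) > params.merge_dist_bp
    cluster_sorted = np.concatenate(([0], np.cumsum(breaks)))
    labels = np.empty(n, dtype=np.int64)
    labels[order] = cluster_sorted
    # relabel so labels increase with genomic position of first member
    first_pos = {}
    pos = np.asarray(positions)
    for i in range(n):
        lab = labels[i]
        if lab not in first_pos:
            first_pos[lab] = pos[i]
    remap = {
        lab: rank
        for rank, lab in enumerate(sorted(first_pos, key=lambda k: first_pos[k]))
    }
    return np.array([remap[lab] for lab in labels], dtype=np.int64)


def _cohort_arrays(samples: list[SampleMethylome]):
    """Union CpG universe per chromosome with per-sample count matrices.

    Returns {chrom: (positions, meth_matrix, total_matrix)} where matrices
    are (n_samples, n_positions); a CpG absent from a sample contributes
    (0, 0) to that sample.
    """
    if not samples:
        raise ValueError("no samples")
    # guard against inconsistent chromosome naming (e.g. "chr1" vs "1"):
    # every non-empty sample must share at least one chromosome with the rest
    chrom_sets = [set(s.df["chrom"].unique()) for s in samples if len(s.df)]
    if len(chrom_sets) > 1:
        shared = set.intersection(*chrom_sets)
        if not shared:
            raise ValueError(
                "samples share no chromosome names; inconsistent naming?"
            )
    chroms: dict[str, set[int]] = {}
    for s in samples:
        for chrom, sub in s.df.groupby("chrom", sort=True):
            chroms.setdefault(chrom, set()).update(sub["pos"].tolist())
    out = {}
    for chrom in sorted(chroms):
        union = np.array(sorted(chroms[chrom]), dtype=np.int64)
        meth = np.zeros((len(samples), union.size), dtype=np.int64)
        total = np.zeros_like(meth)
        for i, s in enumerate(samples):
            sub = s.df[s.df["chrom"] == chrom]
            idx = np.searchsorted(union, sub["pos"].to_numpy())
            meth[i, idx] = sub["n_meth"].to_numpy()
            total[i, idx] = sub["n_total"].to_numpy()
        out[chrom] = (union, meth, total)
    return out


def build_regions(
    samples: list[SampleMethylome],
    params: MeanShiftParams | None = None,
) -> tuple[list[MethylRegion], dict]:
    """Cluster the cohort CpG universe and pool per-sample counts per region.

    The CpG universe is the union of covered positions over all samples (one
    region catalogue for the whole cohort). Regions with fewer than
    ``min_cpg`` member CpGs are dropped and counted in the report.
    Returns (regions sorted by (chrom, start), report dict).
    """
    params = params or MeanShiftParams()
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in cohort")
    arrays = _cohort_arrays(samples)
    regions: list[MethylRegion] = []
    n_dropped = 0
    counter = 0
    for chrom in sorted(arrays):
        union, meth, total = arrays[chrom]
        modes = mean_shift_modes(union, params)
        labels = cluster_by_mode(union, modes, params)
        for lab in range(labels.max() + 1 if labels.size else 0):
            member = labels == lab
            pos = union[member]
            if pos.size < params.min_cpg:
                n_dropped += 1
                continue
            counter += 1
            counts = {
                sid: (int(meth[i, member].sum()), int(total[i, member].sum()))
                for i, sid in enumerate(ids)
            }
            regions.append(
                MethylRegion(
                    region_id=f"region_{counter:06d}",
                    chrom=chrom,
                    start=int(pos[0]),
                    end=int(pos[-1]) + 1,
                    cpg_positions=pos.copy(),
                    mode=float(modes[member].mean()),
                    per_sample_counts=counts,
                )
            )
    report = {"n_regions": len(regions), "n_dropped": n_dropped}
    return regions, report


# the cohort-level entry point most callers want
call_regions = build_regions


@dataclass(frozen=True)
class RegionSummary:
    n_regions: int
    mean_length: float
    median_length: float
    mean_cpg: float
    median_cpg: float


def region_summary(regions: list[MethylRegion]) -> RegionSummary:
    """Length and CpG-count summary of a region catalogue."""
    if not regions:
        raise ValueError("empty region list")
    lengths = np.array([r.end - r.start for r in regions], dtype=float)
    ncpg = np.array([r.n_cpg for r in regions], dtype=float)
    return RegionSummary(
        n_regions=len(regions),
        mean_length=float(lengths.mean()),
        median_length=float(np.median(lengths)),
        mean_cpg=float(ncpg.mean()),
        median_cpg=float(np.median(ncpg)),
    )
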