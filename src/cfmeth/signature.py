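"""PCA over the region-by-sample methylation matrix and signature selection.

Samples are observations, regions variables; the (thin) SVD of the
column-centred samples x regions matrix gives at most n_samples - 1
non-degenerate components. The group-informative component is the one whose
sample scores best separate the two groups (smallest Welch-t p); the
signature is the top fraction of regions by absolute loading on that
component, mapped to genes through the promoter/gene-body annotation rules
and intersected with the E/M reference sets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel
from .dmr import GeneIndex
from .emt import EMTGeneSets
from .regions import MethylRegion

__all__ = [
    "MethylMatrix",
    "PCAResult",
    "SignatureSelection",
    "build_matrix",
    "run_pca",
    "pick_informative_pc",
    "select_top_loadings",
    "map_to_signature",
]


@dataclass
class MethylMatrix:
    """Region-by-sample beta matrix (rows regions, columns samples)."""

    values: pd.DataFrame  # region_id x sample_id, beta in [0, 1]
    n_masked: int = 0  # entries masked by the coverage threshold
    n_dropped_rows: int = 0


@dataclass
class PCAResult:
    components: np.ndarray  # (k, p) orthonormal loadings over regions
    scores: np.ndarray  # (n, k) sample coordinates
    variances: np.ndarray  # (k,) variance per component, non-increasing
    region_ids: list[str]
    sample_ids: list[str]
    mean_: np.ndarray = field(repr=False, default=None)


@dataclass
class SignatureSelection:
    informative_pc: int
    pc_pvalue: float
    selected_regions: list[str]
    loading_cutoff: float
    selected_genes: list[str] = field(default_factory=list)
    emt_signature_genes: list[str] = field(default_factory=list)


def build_matrix(
    regions: list[MethylRegion],
    samples,
    min_coverage: int = 1,
    missing_policy: str = "drop",
) -> MethylMatrix:
    """Per-sample pooled region beta matrix.

    Entries with pooled read total below ``min_coverage`` are masked; rows
    containing a masked entry are dropped (default) or mean-imputed.
    """
    if missing_policy not in ("drop", "impute"):
        raise ValueError("missing_policy must be 'drop' or 'impute'")
    sample_ids = [s.sample_id for s in samples]
    groups = {}
    for s in samples:
        groups.setdefault(s.group, 0)
        groups[s.group] += 1
    if any(v < 2 for v in groups.values()):
        raise ValueError("each group needs >= 2 samples")
    data = np.full((len(regions), len(sample_ids)), np.nan)
    for i, r in enumerate(regions):
        for j, sid in enumerate(sample_ids):
            m, t = r.per_sample_counts.get(sid, (0, 0))
            if t >= max(min_coverage, 1):
                data[i, j] = m / t
    df = pd.DataFrame(
        data, index=[r.region_id for r in regions], columns=sample_ids
    )
    n_masked = int(np.isnan(data).sum())
    n_dropped = 0
    if missing_policy == "drop":
        complete = ~df.isna().any(axis=1)
        n_dropped = int((~complete).sum())
        df = df[complete]
    else:
        row_means = df.mean(axis=1)
        df = df.apply(lambda col: col.fillna(row_means))
        df = df.dropna(how="any")  # rows masked everywhere
    return MethylMatrix(values=df, n_masked=n_masked, n_dropped_rows=n_dropped)


def run_pca(matrix: MethylMatrix | pd.DataFrame, center: bool = True) -> PCAResult:
    """Thin SVD of the column-centred samples x regions matrix.

    Returns loadings (components, orthonormal over regions), sample scores,
    and per-component variances (non-increasing). Raises on an all-constant
    matrix.
    """
    df = matrix.values if isinstance(matrix, MethylMatrix) else matrix
    region_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    X = df.to_numpy(dtype=float).T  # samples x regions
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs >= 2 samples")
    if p < n:
        raise ValueError("PCA expects at least as many regions as samples")
    mean = X.mean(axis=0)
    Xc = X - mean if center else X.copy()
    if not np.any(np.abs(Xc) > 1e-14):
        raise ValueError("degenerate matrix: all rows constant across samples")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    variances = S**2 / (n - 1)
    return PCAResult(
        components=Vt,
        scores=scores,
        variances=variances,
        region_ids=region_ids,
        sample_ids=sample_ids,
        mean_=mean,
    )


def pick_informative_pc(pca: PCAResult, groups) -> tuple[int, float]:
    """Component whose scores best separate the two groups (Welch t-test).

    Returns (component index, two-sided p); ties in p break to the lower
    index. Components with zero score variance in both groups score p = 1.
    """
    g = np.asarray(groups)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a_mask, b_mask = g == levels[0], g == levels[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    top_var = pca.variances[0] if pca.variances.size else 0.0
    best_idx, best_p = 0, np.inf
    for k in range(pca.scores.shape[1]):
        if top_var > 0 and pca.variances[k] <= 1e-12 * top_var:
            p = 1.0  # numerically null component
        else:
            a, b = pca.scores[a_mask, k], pca.scores[b_mask, k]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if p < best_p:
            best_idx, best_p = k, p
    return best_idx, float(best_p)


def select_top_loadings(
    pca: PCAResult, pc: int, fraction: float = 0.025
) -> tuple[list[str], float]:
    """Top ``fraction`` of regions by |loading| on one component.

    Exactly ceil(fraction * n_regions) regions are kept; magnitude ties
    break by region (genomic) order. Returns (region ids, the implied
    absolute-loading cutoff).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if not (0 <= pc < pca.components.shape[0]):
        raise ValueError(f"component index {pc} out of range")
    loadings = np.abs(pca.components[pc])
    n = loadings.size
    k = math.ceil(fraction * n)
    order = np.argsort(-loadings, kind="stable")
    chosen = np.sort(order[:k])
    cutoff = float(loadings[order[k - 1]])
    return [pca.region_ids[i] for i in chosen], cutoff


def map_to_signature(
    selected_region_ids: list[str],
    regions: list[MethylRegion],
    gene_models: list[GeneModel],
    emt_sets: EMTGeneSets | None,
    informative_pc: int = 0,
    pc_pvalue: float = float("nan"),
    loading_cutoff: float = float("nan"),
) -> SignatureSelection:
    """Map selected regions to genes and intersect with the E/M reference.

    Regions annotate to genes by the promoter/gene-body rules; genes are
    deduplicated. emt_signature_genes = selected genes in (E union M).
    """
    index = GeneIndex(gene_models)
    by_id = {r.region_id: r for r in regions}
    genes: list[str] = []
    seen = set()
    for rid in selected_region_ids:
        r = by_id.get(rid)
        if r is None:
            continue
        _, gid, _ = index.annotate(r.chrom, r.start, r.end)
        if gid and gid not in seen:
            seen.add(gid)
            genes.append(gid)
    if emt_sets is not None:
        reference = emt_sets.e_genes | emt_sets.m_genes
        emt_genes = [g for g in genes if g in reference]
    else:
        emt_genes = []
    return SignatureSelection(
        informative_pc=informative_pc,
        pc_pvalue=pc_pvalue,
        selected_regions=list(selected_region_ids),
        loading_cutoff=loading_cutoff,
        selected_genes=genes,
        emt_signature_genes=emt_genes,
    )
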