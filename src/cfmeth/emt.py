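"""EMT-Met scoring: per-sample epithelial/mesenchymal state from methylation.

For one sample, the methylation values (beta, in [0, 1]) of the mesenchymal
gene set and of the epithelial gene set each define an empirical CDF on the
unit interval. The EMT score is

    score = AUC(ECDF of M genes) - AUC(ECDF of E genes)

where each AUC is the area under the right-continuous step function over
[0, 1]. Since the AUC of an ECDF of [0, 1]-valued data equals one minus the
sample mean, the score equals mean(E betas) - mean(M betas); it lies in
[-1, 1] and a positive value calls a mesenchymal phenotype (hypomethylated
mesenchymal genes relative to epithelial ones).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GeneSetCollection
from .dmr import GeneIndex
from .regions import MethylRegion

__all__ = [
    "EMTGeneSets",
    "EMTScore",
    "gene_level_beta",
    "gene_beta_matrix",
    "normalize_sample",
    "ecdf_auc",
    "emt_score",
    "score_cohort",
    "compare_group_scores",
    "roc_auc",
    "mesenchymal_fraction_by_stage",
    "meth_expr_correlation",
]


@dataclass(frozen=True)
class EMTGeneSets:
    """Epithelial and mesenchymal reference gene sets."""

    e_genes: frozenset[str]
    m_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.e_genes or not self.m_genes:
            raise ValueError("both E and M gene sets must be non-empty")
        overlap = self.e_genes & self.m_genes
        if overlap:
            warnings.warn(
                f"E and M sets overlap on {len(overlap)} genes", stacklevel=2
            )

    @classmethod
    def from_collection(
        cls,
        collection: GeneSetCollection,
        e_name: str = "EPI",
        m_name: str = "MES",
    ) -> "EMTGeneSets":
        return cls(frozenset(collection[e_name]), frozenset(collection[m_name]))


@dataclass(frozen=True)
class EMTScore:
    """Per-sample EMT-Met result: score = auc_m - auc_e, in [-1, 1]."""

    sample_id: str
    auc_e: float
    auc_m: float
    score: float
    phenotype: str  # "M" if score > 0 else "E"
    n_e: int = 0  # covered genes contributing to each ECDF
    n_m: int = 0


def gene_level_beta(
    region_betas: dict[str, float] | pd.Series,
    region_genes: dict[str, str],
) -> dict[str, float]:
    """Aggregate region-level beta to gene level (unweighted mean).

    ``region_betas`` maps region id -> beta for one sample; ``region_genes``
    maps region id -> associated gene. Regions without a gene, and genes
    without a covered region, are omitted.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    items = region_betas.items() if isinstance(region_betas, dict) else region_betas.items()
    for rid, b in items:
        gene = region_genes.get(rid, "")
        if gene == "" or b is None or (isinstance(b, float) and np.isnan(b)):
            continue
        sums[gene] = sums.get(gene, 0.0) + float(b)
        counts[gene] = counts.get(gene, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}


def gene_beta_matrix(
    regions: list[MethylRegion],
    gene_models: list[GeneModel],
) -> pd.DataFrame:
    """Genes x samples matrix of gene-level beta from a region catalogue.

    Each region is assigned to a gene by the promoter/gene-body annotation
    rules; a gene's value per sample is the unweighted mean beta over its
    associated regions covered in that sample. NaN where no region covers
    the gene in a sample.
    """
    index = GeneIndex(gene_models)
    region_genes: dict[str, str] = {}
    for r in regions:
        ann, gid, _ = index.annotate(r.chrom, r.start, r.end)
        if gid:
            region_genes[r.region_id] = gid
    sample_ids: list[str] = sorted(
        {sid for r in regions for sid in r.per_sample_counts}
    )
    columns = {}
    for sid in sample_ids:
        betas = {
            r.region_id: r.per_sample_beta.get(sid, float("nan")) for r in regions
        }
        columns[sid] = gene_level_beta(betas, region_genes)
    genes = sorted({g for col in columns.values() for g in col})
    return pd.DataFrame(
        {sid: [columns[sid].get(g, np.nan) for g in genes] for sid in sample_ids},
        index=pd.Index(genes, name="gene_id"),
    )


def normalize_sample(beta_vector, method: str = "rank_uniform"):
    """Per-sample normalization of a gene -> beta mapping.

    rank_uniform maps the i-th smallest of n values to (i - 0.5)/n with
    average ranks on ties; minmax rescales to span [0, 1]; none is identity.
    """
    if method not in ("none", "rank_uniform", "minmax"):
        raise ValueError(f"unknown normalization method {method!r}")
    keys = list(beta_vector.keys()) if isinstance(beta_vector, dict) else list(beta_vector.index)
    vals = np.asarray(
        [beta_vector[k] for k in keys], dtype=float
    )
    if vals.size == 0:
        raise ValueError("empty beta vector")
    if method == "none":
        out = vals
    elif method == "rank_uniform":
        out = (stats.rankdata(vals, method="average") - 0.5) / vals.size
    else:  # minmax
        lo, hi = vals.min(), vals.max()
        out = np.full_like(vals, 0.5) if hi == lo else (vals - lo) / (hi - lo)
    return dict(zip(keys, out.tolist()))


def ecdf_auc(values) -> float:
    """Area under the right-continuous ECDF step function over [0, 1].

    Values must lie in [0, 1]; equals 1 - mean(values), but computed by
    explicit step integration.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf_auc of empty values")
    if np.any(v < 0) or np.any(v > 1) or np.any(np.isnan(v)):
        raise ValueError("values must lie in [0, 1]")
    xs = np.sort(v)
    n = xs.size
    # F(x) = (i+1)/n on [xs[i], xs[i+1]); integrate each step up to 1
    edges = np.concatenate((xs, [1.0]))
    widths = np.diff(edges)
    heights = np.arange(1, n + 1) / n
    return float(np.sum(widths * heights))


def emt_score(beta_vector, emt_sets: EMTGeneSets, sample_id: str = "") -> EMTScore:
    """EMT-Met score of one sample: AUC_ecdf(M) - AUC_ecdf(E).

    ``beta_vector`` maps gene -> methylation value in [0, 1]; only genes in
    the respective set that are present contribute. Positive score (M-gene
    ECDF above E-gene ECDF, i.e. M genes less methylated) calls phenotype M.
    """
    getter = beta_vector.get if isinstance(beta_vector, dict) else (
        lambda g, d=None: beta_vector[g] if g in beta_vector.index else d
    )
    e_vals = [getter(g) for g in sorted(emt_sets.e_genes)]
    m_vals = [getter(g) for g in sorted(emt_sets.m_genes)]
    e_vals = [v for v in e_vals if v is not None and not np.isnan(v)]
    m_vals = [v for v in m_vals if v is not None and not np.isnan(v)]
    if not e_vals:
        raise ValueError("no covered epithelial genes")
    if not m_vals:
        raise ValueError("no covered mesenchymal genes")
    auc_e = ecdf_auc(e_vals)
    auc_m = ecdf_auc(m_vals)
    score = auc_m - auc_e
    return EMTScore(
        sample_id=sample_id,
        auc_e=auc_e,
        auc_m=auc_m,
        score=score,
        phenotype="M" if score > 0 else "E",
        n_e=len(e_vals),
        n_m=len(m_vals),
    )


def score_cohort(
    beta_matrix: pd.DataFrame,
    emt_sets: EMTGeneSets,
    normalize: str = "rank_uniform",
) -> list[EMTScore]:
    """Score every sample (column) of a genes x samples beta matrix."""
    scores = []
    for sid in beta_matrix.columns:
        col = beta_matrix[sid].dropna()
        vec = dict(zip(col.index, col.to_numpy(float)))
        vec = normalize_sample(vec, normalize)
        scores.append(emt_score(vec, emt_sets, sample_id=str(sid)))
    return scores


def compare_group_scores(scores, groups, test: str = "welch") -> float:
    """Two-sided p for a group difference in EMT scores.

    ``scores``: per-sample score values; ``groups``: parallel labels with
    exactly two levels, each with >= 2 samples. Welch t-test by default,
    Mann-Whitney optional. With zero variance in both groups, p = 1 for
    equal means and 0 in the separated limit.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    levels = sorted(set(g.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a, b = s[g == levels[0]], s[g == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if test == "welch":
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test {test!r}")


def roc_auc(scores, labels, positive=None):
    """ROC AUC by the rank (Mann-Whitney) formulation with tie half-credit.

    Returns (auc, curve) where curve is an (n_thresholds + 1, 2) array of
    (FPR, TPR) points from (0, 0) to (1, 1), one step per distinct score.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive is None:
        positive = classes[1]
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(s, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)
    # curve: sweep thresholds from high to low
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate((distinct, [s.size - 1]))
    tp = np.cumsum(pos_sorted)[cut]
    fp = np.cumsum(~pos_sorted)[cut]
    curve = np.column_stack(
        (
            np.concatenate(([0.0], fp / n_neg)),
            np.concatenate(([0.0], tp / n_pos)),
        )
    )
    return float(auc), curve


def mesenchymal_fraction_by_stage(scores, stages) -> dict[str, float]:
    """Per-stage fraction of samples with a mesenchymal call (score > 0)."""
    s = np.asarray(scores, dtype=float)
    out: dict[str, float] = {}
    stage_arr = np.asarray(stages, dtype=object)
    for stage in sorted({x for x in stage_arr.tolist() if x is not None}):
        member = stage_arr == stage
        if member.sum() == 0:
            continue
        out[str(stage)] = float((s[member] > 0).mean())
    return out


def meth_expr_correlation(meth_vector, expr_vector):
    """Pearson r and two-sided p between paired methylation and expression."""
    m = np.asarray(meth_vector, dtype=float)
    e = np.asarray(expr_vector, dtype=float)
    if m.shape != e.shape or m.ndim != 1:
        raise ValueError("vectors must be 1-D and the same length")
    if m.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.std(m) == 0 or np.std(e) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(m, e)
    return float(r), float(p)
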