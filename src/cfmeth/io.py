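"""Readers and writers for the pipeline's external formats.

Supported formats: methylation-extractor bedGraph dialect (per-CpG counts),
BED6 gene models, GMT gene sets, TSV sample sheets, and the pipeline's own
BED/TSV interchange tables. Everything is UTF-8, tab-separated, 0-based
half-open.
"""
from __future__ import annotations

import math
import os
from typing import Iterable, TYPE_CHECKING

import numpy as np
import pandas as pd

from .core import GeneModel, GeneSetCollection, SampleMethylome

if TYPE_CHECKING:  # pragma: no cover
    from .dmr import DMRecord
    from .emt import EMTScore
    from .regions import MethylRegion

__all__ = [
    "read_cpg_calls",
    "read_gene_models",
    "read_gmt",
    "read_sample_sheet",
    "load_cohort",
    "write_regions_bed",
    "read_regions_bed",
    "write_dmrs_tsv",
    "write_scores_tsv",
    "write_outputs",
]


def read_cpg_calls(
    path: str | os.PathLike,
    sample_id: str,
    group: str,
    stage: str | None = None,
) -> SampleMethylome:
    """Parse a methylation-extractor bedGraph file into a SampleMethylome.

    Expected columns: chrom, start, end, methylation percent, n_meth,
    n_unmeth. The percent column is ignored; beta is recomputed from the
    integer counts. An optional ``track ...`` header line is skipped.
    Output is sorted by (chrom, pos); duplicate positions are an error.
    """
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    totals: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, _pct, meth_s, unmeth_s = fields[:6]
            try:
                start = int(start_s)
                end = int(end_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer field ({exc})"
                ) from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative read count")
            if end != start + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected single-base interval, "
                    f"got [{start}, {end})"
                )
            chroms.append(chrom)
            poss.append(start)
            meths.append(n_meth)
            totals.append(n_meth + n_unmeth)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "pos": pd.Series(poss, dtype=np.int64),
            "n_meth": pd.Series(meths, dtype=np.int64),
            "n_total": pd.Series(totals, dtype=np.int64),
        }
    )
    try:
        return SampleMethylome(sample_id, group, df, stage=stage)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read BED6 gene models; TSS/TES are derived strand-aware."""
    genes: list[GeneModel] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED6 requires 6 fields "
                    f"(missing strand?)"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            try:
                genes.append(GeneModel(name, chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return genes


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file (set name, description, members...). One set per line;
    duplicate members on a line collapse; a repeated set name is an error."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields "
                    f"(name, description, members)"
                )
            name = fields[0]
            members = frozenset(g for g in fields[2:] if g != "")
            if name in sets:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            sets[name] = members
    return GeneSetCollection(sets)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet: TSV with header sample_id, group[, stage][, path]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in sample sheet")
    return df


def load_cohort(sheet_path: str | os.PathLike) -> list[SampleMethylome]:
    """Load every sample referenced in a sample sheet (``path`` column required).

    Relative paths are resolved against the sheet's directory.
    """
    sheet = read_sample_sheet(sheet_path)
    if "path" not in sheet.columns:
        raise ValueError(f"{sheet_path}: sample sheet has no 'path' column")
    base = os.path.dirname(os.fspath(sheet_path))
    samples = []
    for row in sheet.itertuples(index=False):
        p = row.path
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        stage = getattr(row, "stage", None)
        if stage is not None and (pd.isna(stage) or stage == "NA"):
            stage = None
        samples.append(read_cpg_calls(p, row.sample_id, row.group, stage=stage))
    return samples


# ---------------------------------------------------------------------------
# writers


def write_regions_bed(regions: Iterable["MethylRegion"], path) -> None:
    """Write regions as BED: chrom, start, end, region_id, n_cpg, strand('.')."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.n_cpg}\t.\n"
            )


def read_regions_bed(path) -> pd.DataFrame:
    """Read a regions BED back into a frame (chrom, start, end, region_id, n_cpg)."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: line {lineno}: expected >= 5 fields")
            rows.append(
                (fields[0], int(fields[1]), int(fields[2]), fields[3], int(fields[4]))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "region_id", "n_cpg"]
    )


_DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_cpg",
    "p_value",
    "mean_diff",
    "direction",
    "annotation",
    "gene_id",
    "tss_distance",
]


def write_dmrs_tsv(dmrs: Iterable["DMRecord"], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_DMR_COLUMNS) + "\n")
        for d in dmrs:
            tssd = "" if d.tss_distance is None else str(int(d.tss_distance))
            fh.write(
                f"{d.region.chrom}\t{d.region.start}\t{d.region.end}\t"
                f"{d.region.n_cpg}\t{d.p_value:.6g}\t{d.mean_diff:.6f}\t"
                f"{d.direction}\t{d.annotation}\t{d.gene_id}\t{tssd}\n"
            )


def write_scores_tsv(scores: Iterable["EMTScore"], path, groups=None) -> None:
    """Write EMT scores; ``groups`` maps sample_id -> group label (optional)."""
    groups = groups or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tauc_e\tauc_m\temt_score\tphenotype\n")
        for s in scores:
            g = groups.get(s.sample_id, "")
            fh.write(
                f"{s.sample_id}\t{g}\t{s.auc_e:.6f}\t{s.auc_m:.6f}\t"
                f"{s.score:.6f}\t{s.phenotype}\n"
            )


def write_outputs(obj, path, **kwargs) -> None:
    """Dispatch writer: a list of regions, DMRs, or EMT scores."""
    seq = list(obj)
    if not seq:
        # empty collection: caller must disambiguate via kind=
        kind = kwargs.get("kind")
        if kind == "regions":
            write_regions_bed(seq, path)
        elif kind == "dmrs":
            write_dmrs_tsv(seq, path)
        elif kind == "scores":
            write_scores_tsv(seq, path, kwargs.get("groups"))
        else:
            raise ValueError("empty collection: pass kind='regions'|'dmrs'|'scores'")
        return
    head = seq[0]
    if hasattr(head, "cpg_positions"):
        write_regions_bed(seq, path)
    elif hasattr(head, "p_value") and hasattr(head, "direction"):
        write_dmrs_tsv(seq, path)
    elif hasattr(head, "auc_e"):
        write_scores_tsv(seq, path, kwargs.get("groups"))
    else:
        raise TypeError(f"do not know how to write {type(head).__name__}")


def write_bedgraph(sample: SampleMethylome, path) -> None:
    """Write a SampleMethylome in the extractor bedGraph dialect (6 columns).

    The percent column is derived from the counts; 0.0 at zero coverage.
    """
    df = sample.df
    with open(path, "w", encoding="utf-8") as fh:
        for row in df.itertuples(index=False):
            total = int(row.n_total)
            meth = int(row.n_meth)
            pct = 100.0 * meth / total if total > 0 else 0.0
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{pct:.4f}\t"
                f"{meth}\t{total - meth}\n"
            )
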