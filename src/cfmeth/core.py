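"""Shared domain containers for the cfBS methylation pipeline.

Coordinates are 0-based half-open everywhere (BED convention). A CpG is
tracked on its cytosine position only; symmetric-strand collapsing is
assumed to have happened upstream in the methylation extractor.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "CpGRecord",
    "SampleMethylome",
    "GeneModel",
    "GeneSetCollection",
]


@dataclass(frozen=True)
class CpGRecord:
    """A single CpG methylation call: methylated / total read counts."""

    chrom: str
    pos: int
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_total < 0:
            raise ValueError(
                f"negative count at {self.chrom}:{self.pos} "
                f"(n_meth={self.n_meth}, n_total={self.n_total})"
            )
        if self.n_meth > self.n_total:
            raise ValueError(
                f"n_meth > n_total at {self.chrom}:{self.pos} "
                f"({self.n_meth} > {self.n_total})"
            )

    @property
    def beta(self) -> float:
        """Methylation level n_meth / n_total; NaN when the site is uncovered."""
        if self.n_total == 0:
            return math.nan
        return self.n_meth / self.n_total


class SampleMethylome:
    """Per-CpG methylation calls for one sample.

    Holds a DataFrame with columns ``chrom, pos, n_meth, n_total`` sorted by
    (chrom, pos) with unique positions. ``beta`` is always recomputed from
    the stored counts, never cached from an input file.
    """

    def __init__(
        self,
        sample_id: str,
        group: str,
        df: pd.DataFrame,
        stage: str | None = None,
        _validated: bool = False,
    ) -> None:
        self.sample_id = sample_id
        self.group = group
        self.stage = stage
        df = df.reset_index(drop=True)
        if not _validated:
            df = self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        required = ["chrom", "pos", "n_meth", "n_total"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"methylome frame missing columns: {missing}")
        df = df[required].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_total"] = df["n_total"].astype(np.int64)
        if (df["n_meth"] < 0).any() or (df["n_total"] < 0).any():
            raise ValueError("negative read counts")
        if (df["n_meth"] > df["n_total"]).any():
            raise ValueError("n_meth exceeds n_total")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise ValueError(f"duplicate CpG position {dup['chrom']}:{dup['pos']}")
        return df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def beta(self) -> pd.Series:
        """Per-CpG methylation ratio; NaN at zero coverage."""
        total = self.df["n_total"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(total > 0, self.df["n_meth"].to_numpy(float) / total, np.nan)
        return pd.Series(b, index=self.df.index, name="beta")

    def records(self) -> Iterator[CpGRecord]:
        for row in self.df.itertuples(index=False):
            yield CpGRecord(row.chrom, int(row.pos), int(row.n_meth), int(row.n_total))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SampleMethylome({self.sample_id!r}, group={self.group!r}, "
            f"n_cpg={len(self.df)})"
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS/TES (0-based half-open span)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class GeneSetCollection:
    """Named gene sets (e.g. epithelial / mesenchymal signatures, pathways)."""

    def __init__(self, sets: dict[str, frozenset[str]]) -> None:
        for name, members in sets.items():
            if any((not isinstance(g, str)) or g == "" for g in members):
                raise ValueError(f"gene set {name!r} has empty/non-string members")
        self.sets: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in sets.items()
        }

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)
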