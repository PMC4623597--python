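"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``,
the BED convention. Strand is ``'+'`` or ``'-'``; intervals reported by
the cross-species mapper are always given on the plus strand of the
target assembly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.start, iv.end, iv.strand) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    strand = df["strand"] if "strand" in df.columns else ["+"] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strand)
    ]


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping (>= 1 bp) intervals per chromosome.

    Returns a sorted BED-like frame; book-ended (touching) intervals are
    left separate.
    """
    if len(df) == 0:
        return df.loc[:, ["chrom", "start", "end"]].copy()
    out_rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        cur_s = cur_e = None
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict overlap
                cur_e = max(cur_e, e)
            else:
                out_rows.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        out_rows.append((chrom, int(cur_s), int(cur_e)))
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end"])


def nearest_distance(pos: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Distance from a point to the nearest of a set of intervals (0 if inside)."""
    if len(starts) == 0:
        raise ValueError("empty interval set")
    d = np.where(
        (pos >= starts) & (pos < ends),
        0,
        np.minimum(np.abs(starts - pos), np.abs(ends - 1 - pos)),
    )
    return int(d.min())
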