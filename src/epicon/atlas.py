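"""Cross-species union atlas of regulatory elements.

Peaks from each species are lifted to the other assembly; peaks whose
cross-mappings overlap reciprocally collapse into a single genetically
conserved locus, peaks that map into a region with no partner peak remain
genetically conserved (the partner species' signal is quantifiable at the
mapped interval but may be epigenetically inactive), and unmappable peaks
become species-only loci.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .chains import DEFAULT_MIN_MAPPED_FRACTION, ChainsLike
from .intervals import GenomicInterval, frame_to_intervals, merge_intervals
from .orthology import AssayScanParams, iterative_ortholog_search

GENETIC_STATUSES = ("conserved", "human-only", "mouse-only")


@dataclass
class AtlasLocus:
    atlas_id: str
    human: Optional[GenomicInterval]
    mouse: Optional[GenomicInterval]
    genetic_status: str
    human_peak: bool = False
    mouse_peak: bool = False

    def __post_init__(self) -> None:
        both = self.human is not None and self.mouse is not None
        if (self.genetic_status == "conserved") != both:
            raise ValueError("conserved iff both species intervals present")


@dataclass
class UnionAtlas:
    """Merged cross-species locus set with genetic-conservation annotations."""

    loci: list[AtlasLocus]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.loci:
            rows.append(
                dict(
                    atlas_id=l.atlas_id,
                    genetic_status=l.genetic_status,
                    human_chrom=l.human.chrom if l.human else None,
                    human_start=l.human.start if l.human else -1,
                    human_end=l.human.end if l.human else -1,
                    mouse_chrom=l.mouse.chrom if l.mouse else None,
                    mouse_start=l.mouse.start if l.mouse else -1,
                    mouse_end=l.mouse.end if l.mouse else -1,
                    human_peak=l.human_peak,
                    mouse_peak=l.mouse_peak,
                )
            )
        return pd.DataFrame(rows)

    @property
    def n_conserved(self) -> int:
        return sum(l.genetic_status == "conserved" for l in self.loci)


def _merge_with_warning(peaks: pd.DataFrame, species: str) -> pd.DataFrame:
    merged = merge_intervals(peaks)
    if len(merged) < len(peaks):
        warnings.warn(
            f"{len(peaks) - len(merged)} overlapping {species} peaks merged "
            "before cross-species mapping",
            stacklevel=3,
        )
    return merged.reset_index(drop=True)


def build_union_atlas(
    peaks_h: pd.DataFrame,
    peaks_m: pd.DataFrame,
    chains_h2m: ChainsLike,
    chains_m2h: ChainsLike,
    params: AssayScanParams,
    min_mapped_fraction: float = DEFAULT_MIN_MAPPED_FRACTION,
) -> UnionAtlas:
    """Build the union atlas from per-species peak sets (BED-like frames).

    Reciprocal collapse requires >= 1 bp overlap of a cross-mapped interval
    with the partner peak; many-to-one conflicts are resolved by largest
    total overlap, then lowest coordinate. Every input peak is represented
    exactly once.
    """
    peaks_h = _merge_with_warning(peaks_h, "human")
    peaks_m = _merge_with_warning(peaks_m, "mouse")
    ivs_h = frame_to_intervals(peaks_h)
    ivs_m = frame_to_intervals(peaks_m)

    def scan(iv: GenomicInterval, chains: ChainsLike):
        p = params
        if p.subwindow > len(iv):
            p = AssayScanParams(p.assay, p.locus_span, step=1, subwindow=len(iv))
        return iterative_ortholog_search(iv, chains, p, min_mapped_fraction)

    maps_h = [scan(iv, chains_h2m) for iv in ivs_h]
    maps_m = [scan(iv, chains_m2h) for iv in ivs_m]

    # Overlap lookup over the (merged, hence disjoint) per-species peaks.
    def make_index(ivs):
        idx: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for k, iv in enumerate(ivs):
            by_chrom.setdefault(iv.chrom, []).append(k)
        for chrom, ks in by_chrom.items():
            ks = sorted(ks, key=lambda k: ivs[k].start)
            starts = np.array([ivs[k].start for k in ks])
            ends = np.array([ivs[k].end for k in ks])
            idx[chrom] = (starts, ends, np.array(ks))
        return idx

    def overlapping(idx, iv: GenomicInterval):
        if iv.chrom not in idx:
            return []
        starts, ends, ks = idx[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return list(ks[lo:hi])

    index_h = make_index(ivs_h)
    index_m = make_index(ivs_m)

    # Candidate reciprocal pairs.
    candidates = []
    for i, (iv_h, res_h) in enumerate(zip(ivs_h, maps_h)):
        if res_h.mapped is None:
            continue
        for j in overlapping(index_m, res_h.mapped):
            res_m = maps_m[j]
            if res_m.mapped is None:
                continue
            ov = res_h.mapped.overlap_len(ivs_m[j])
            rev = res_m.mapped.overlap_len(iv_h)
            if ov > 0 and rev > 0:
                candidates.append((ov + rev, i, j))
    # Greedy resolution: largest overlap first, then lowest coordinates.
    candidates.sort(key=lambda t: (-t[0], ivs_h[t[1]].start, ivs_m[t[2]].start))
    paired_h: dict[int, int] = {}
    paired_m: dict[int, int] = {}
    for _, i, j in candidates:
        if i not in paired_h and j not in paired_m:
            paired_h[i] = j
            paired_m[j] = i

    loci: list[AtlasLocus] = []
    n = 0

    def next_id() -> str:
        nonlocal n
        n += 1
        return f"atlas{n:06d}"

    for i, (iv_h, res_h) in enumerate(zip(ivs_h, maps_h)):
        if i in paired_h:
            j = paired_h[i]
            loci.append(
                AtlasLocus(next_id(), iv_h, ivs_m[j], "conserved", True, True)
            )
        elif res_h.mapped is not None:
            loci.append(
                AtlasLocus(next_id(), iv_h, res_h.mapped, "conserved", True, False)
            )
        else:
            loci.append(AtlasLocus(next_id(), iv_h, None, "human-only", True, False))
    for j, (iv_m, res_m) in enumerate(zip(ivs_m, maps_m)):
        if j in paired_m:
            continue
        if res_m.mapped is not None:
            loci.append(
                AtlasLocus(next_id(), res_m.mapped, iv_m, "conserved", False, True)
            )
        else:
            loci.append(AtlasLocus(next_id(), None, iv_m, "mouse-only", False, True))
    return UnionAtlas(loci)
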