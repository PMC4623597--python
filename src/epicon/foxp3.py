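"""Conservation of Foxp3 binding and its repressive footprint.

Foxp3-bound sites at genetically conserved loci are classified as bound
in both species, human-only or mouse-only by an occupancy floor; sites
below the floor in both species lack robust quantification and are
excluded. Binding classes are related to Treg-vs-effector acetylation
change (two-sample t vs the all-acetylated background), to repression of
nearby genes (one-sided KS), and to presence of the forkhead DNA motif
against a flanking-sequence background (Fisher's exact test).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chains import ChainsLike, map_interval
from .intervals import GenomicInterval

BINDING_CLASSES = ("both", "human_only", "mouse_only")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Core forkhead-box consensus scanned by default.
FORKHEAD_CONSENSUS = "RYAAAYA"


@dataclass(frozen=True)
class MotifModel:
    """IUPAC consensus motif, scanned on both strands."""

    pattern: str = FORKHEAD_CONSENSUS

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes: {sorted(bad)}")

    def regex(self) -> re.Pattern:
        return re.compile("".join(IUPAC[c] for c in self.pattern.upper()))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.pattern.upper().translate(COMPLEMENT)[::-1])

    def present(self, seq: str) -> bool:
        s = seq.upper()
        return bool(self.regex().search(s) or self.reverse_complement().regex().search(s))


def classify_binding_conservation(
    sites_h: pd.DataFrame,
    sites_m: pd.DataFrame,
    chains_h2m: ChainsLike,
    floor: float = 1.0,
    min_mapped_fraction: float = 0.95,
) -> pd.DataFrame:
    """Binding-conservation class per orthologously mappable human site.

    ``sites_h``/``sites_m`` need chrom, start, end, occupancy (RPM).
    Each human site is lifted to the mouse assembly; the mouse occupancy
    is the maximum over mouse sites overlapping the mapped interval (0 if
    none). Classes: both / human_only / mouse_only by the robust-
    quantification ``floor``; sites below the floor in both species get
    class "excluded"; unmappable sites get class "unmappable" and are
    reported separately from the conserved-class analysis.
    """
    rows = []
    for i, row in enumerate(sites_h.itertuples(index=False)):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        res = map_interval(iv, chains_h2m, min_mapped_fraction)
        occ_h = float(row.occupancy)
        if res.mapped is None:
            rows.append(dict(site=i, occupancy_human=occ_h,
                             occupancy_mouse=np.nan, cls="unmappable"))
            continue
        m = res.mapped
        hit = sites_m[
            (sites_m["chrom"] == m.chrom)
            & (sites_m["start"] < m.end)
            & (sites_m["end"] > m.start)
        ]
        occ_m = float(hit["occupancy"].max()) if len(hit) else 0.0
        if occ_h >= floor and occ_m >= floor:
            cls = "both"
        elif occ_h >= floor:
            cls = "human_only"
        elif occ_m >= floor:
            cls = "mouse_only"
        else:
            cls = "excluded"
        rows.append(dict(site=i, occupancy_human=occ_h, occupancy_mouse=occ_m, cls=cls))
    return pd.DataFrame(rows)


def acetylation_change_by_class(
    class_lfc: Mapping[str, Sequence[float]],
    background_lfc: Sequence[float],
) -> pd.DataFrame:
    """Two-sample t of per-class acetylation change vs the all-loci background.

    Star coding: * p<0.05, ** p<0.01, *** p<0.001.
    """
    bg = np.asarray(background_lfc, float)
    rows = []
    for cls, vals in class_lfc.items():
        v = np.asarray(vals, float)
        if len(v) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 loci")
        if np.ptp(v) == 0 and np.ptp(bg) == 0:
            raise ValueError("degenerate variance in class and background")
        t, p = stats.ttest_ind(v, bg, equal_var=False)
        stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append(dict(cls=cls, n=len(v), mean_lfc=float(v.mean()),
                         t=float(t), p=float(p), stars=stars))
    return pd.DataFrame(rows)


def _region_sequences(
    sites: pd.DataFrame, genome: Mapping[str, str], flank: int
) -> tuple[list[str], list[str]]:
    """Site sequences and pooled flanking sequences (two per site)."""
    site_seqs, flank_seqs = [], []
    for row in sites.itertuples(index=False):
        seq = genome[row.chrom]
        site_seqs.append(str(seq[int(row.start):int(row.end)]))
        for lo, hi in (
            (int(row.start) - flank, int(row.start)),
            (int(row.end), int(row.end) + flank),
        ):
            lo_c, hi_c = max(0, lo), min(len(seq), hi)
            if (lo_c, hi_c) != (lo, hi):
                warnings.warn(
                    f"flank of site {row.chrom}:{row.start}-{row.end} truncated "
                    "at contig end",
                    stacklevel=3,
                )
            if hi_c > lo_c:
                flank_seqs.append(str(seq[lo_c:hi_c]))
    return site_seqs, flank_seqs


def motif_enrichment(
    sites: pd.DataFrame,
    genome: Mapping[str, str],
    motif: MotifModel = MotifModel(),
    flank: int = 200,
) -> dict:
    """Motif presence in binding sites vs flanking background (Fisher exact).

    The 2x2 table counts regions (site vs flank) with/without at least one
    motif match on either strand; both flanks of every site contribute to
    the pooled background. Returns the sample odds ratio and two-sided p.
    """
    site_seqs, flank_seqs = _region_sequences(sites, genome, flank)
    a = sum(motif.present(s) for s in site_seqs)       # site, motif+
    b = len(site_seqs) - a                             # site, motif-
    c = sum(motif.present(s) for s in flank_seqs)      # flank, motif+
    d = len(flank_seqs) - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return dict(table=table, odds_ratio=float(odds), p=float(p),
                n_sites=len(site_seqs), n_flanks=len(flank_seqs))


def repression_by_binding(
    class_gene_lfc: Mapping[str, Sequence[float]],
    all_gene_lfc: Sequence[float],
) -> pd.DataFrame:
    """One-sided KS: are genes near bound sites shifted down vs all expressed genes?

    ``alternative='greater'`` (bound CDF above background) corresponds to
    repression of the bound set.
    """
    bg = np.asarray(all_gene_lfc, float)
    rows = []
    for cls, vals in class_gene_lfc.items():
        v = np.asarray(vals, float)
        if len(v) < 3:
            warnings.warn(f"class {cls!r} has {len(v)} genes; KS skipped", stacklevel=2)
            rows.append(dict(cls=cls, n=len(v), ks_d=np.nan, p=np.nan))
            continue
        d, p = stats.ks_2samp(v, bg, alternative="greater")
        rows.append(dict(cls=cls, n=len(v), ks_d=float(d), p=float(p)))
    return pd.DataFrame(rows)
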