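"""Disease-risk SNP enrichment in element-derived regions.

GWAS-catalog variants are intersected with broad regions around
cell-type-specific regulatory elements (a crude linkage-disequilibrium
correction: one merged region per haplotype-scale neighbourhood, variants
counted once per region) and enrichment of a disease set is referred to a
one-tailed hypergeometric null over all catalogued disease variants.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals

#: Nested conservation categories of risk-harbouring elements, outermost first.
CONSERVATION_CATEGORIES = (
    "non_conserved",
    "conserved",
    "lineage_specific_human",
    "lineage_specific_both",
)


@dataclass(frozen=True)
class DiseaseSet:
    """A named set of GWAS traits (autoimmune, metabolic, psychiatric, ...)."""

    name: str
    traits: tuple

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("disease set must contain >= 1 trait")


def filter_studies(catalog: pd.DataFrame, min_snps: int = 5) -> pd.DataFrame:
    """Keep studies reporting strictly more than ``min_snps`` independent SNPs."""
    counts = catalog.groupby("study")["variant"].nunique()
    keep = counts[counts > min_snps].index
    return catalog[catalog["study"].isin(keep)].reset_index(drop=True)


def expand_risk_regions(
    elements: pd.DataFrame,
    gene_models: Optional[pd.DataFrame] = None,
    span: int = 100_000,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Broad haplotype-scale regions around elements, merged when overlapping.

    Each element expands by ``span`` bp on both sides; when its most
    proximal gene body extends beyond that window the region grows to
    cover the gene body too. Coordinates are clipped at contig bounds.
    """
    rows = []
    for el in elements.itertuples(index=False):
        lo = el.start - span
        hi = el.end + span
        if gene_models is not None and len(gene_models):
            sub = gene_models[gene_models["chrom"] == el.chrom]
            if len(sub):
                center = (el.start + el.end) // 2
                dist = np.abs(sub["tss"].to_numpy() - center)
                g = sub.iloc[int(np.argmin(dist))]
                lo = min(lo, int(g["body_start"]))
                hi = max(hi, int(g["body_end"]))
        lo = max(0, lo)
        if chrom_sizes is not None:
            hi = min(hi, chrom_sizes[el.chrom])
        rows.append((el.chrom, int(lo), int(hi)))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return merge_intervals(regions)


def _in_regions(catalog: pd.DataFrame, regions: pd.DataFrame) -> pd.Series:
    hit = pd.Series(False, index=catalog.index)
    for chrom, sub in regions.groupby("chrom"):
        sel = catalog["chrom"] == chrom
        if not sel.any():
            continue
        pos = catalog.loc[sel, "pos"].to_numpy()
        inside = np.zeros(len(pos), dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            inside |= (pos >= s) & (pos < e)
        hit.loc[sel] = inside
    return hit


def enrichment_test(
    disease_set: DiseaseSet,
    catalog: pd.DataFrame,
    regions: pd.DataFrame,
) -> dict:
    """One-tailed hypergeometric enrichment of a disease set in regions.

    Universe N = all catalogued variants, K = catalogued variants inside
    the regions, n = variants of the disease set, k = disease variants
    inside; p = P(X >= k). Variants are deduplicated so each counts once.
    """
    cat = catalog.drop_duplicates("variant")
    dz = cat[cat["trait"].isin(disease_set.traits)]
    if len(dz) == 0:
        raise ValueError(f"disease set {disease_set.name!r} has no catalog variants")
    inside = _in_regions(cat, regions)
    N = len(cat)
    K = int(inside.sum())
    n = len(dz)
    k = int(inside.loc[dz.index].sum())
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return dict(name=disease_set.name, N=N, K=K, n=n, k=k, p=p)


def conservation_partition(
    risk_elements: pd.DataFrame,
    disease_col: str = "disease_set",
) -> pd.DataFrame:
    """Counts of risk-harbouring elements per nested conservation category.

    ``risk_elements`` needs ``genetic_status``, ``class_human``,
    ``class_mouse`` plus a disease-set column. Categories are nested:
    lineage-specific-in-both implies lineage-specific-in-human implies
    genetically conserved; each element is counted in its deepest
    category. Unannotated elements land in "unknown" with a warning.
    """
    def category(row) -> str:
        gs = row.get("genetic_status")
        if pd.isna(gs) or gs is None:
            return "unknown"
        if gs != "conserved":
            return "non_conserved"
        ch, cm = row.get("class_human"), row.get("class_mouse")
        h_ls = ch in ("up", "down")
        m_ls = cm in ("up", "down")
        if h_ls and m_ls:
            return "lineage_specific_both"
        if h_ls:
            return "lineage_specific_human"
        return "conserved"

    cats = risk_elements.apply(category, axis=1)
    if (cats == "unknown").any():
        warnings.warn(
            f"{int((cats == 'unknown').sum())} risk elements lack conservation "
            "annotations",
            stacklevel=2,
        )
    df = risk_elements.assign(category=cats)
    out = (
        df.groupby([disease_col, "category"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = out.groupby(disease_col)["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    return out
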