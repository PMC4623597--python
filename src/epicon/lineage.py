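"""Lineage-specificity classification and its cross-species conservation.

An element is lineage-specific in a species when its Treg-vs-effector
log2 fold change of acetylation exceeds a threshold. Conservation of
lineage-specificity is tested by one-sided hypergeometric overlap of the
per-species up (or down) sets over the universe of genetically conserved
loci, element classes are related to nearby gene-expression changes by
Kolmogorov-Smirnov comparisons, and the mobility analysis asks whether a
lineage-specific element lost at the orthologous position re-emerges
elsewhere in the same genic locus.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import LOG_PSEUDOCOUNT

DIRECTIONS = ("up", "down", "ns")


def lfc(rpm_a, rpm_b) -> np.ndarray:
    """log2[(RPM_a + 0.5) / (RPM_b + 0.5)].

    The symmetric pseudocount shrinks fold changes of weak peaks toward
    zero, damping read-count noise.
    """
    a = np.asarray(rpm_a, dtype=float)
    b = np.asarray(rpm_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("RPM values must be >= 0")
    return np.log2((a + LOG_PSEUDOCOUNT) / (b + LOG_PSEUDOCOUNT))


def _direction(values: np.ndarray, tau: float) -> np.ndarray:
    out = np.where(values >= tau, "up", np.where(values <= -tau, "down", "ns"))
    return out.astype(object)


def classify_specificity(
    records: pd.DataFrame, tau: float = 1.0
) -> pd.DataFrame:
    """Per-species and combined lineage-specificity labels.

    ``records`` needs ``lfc_human``/``lfc_mouse`` (NaN for the missing
    species of a species-only locus) and optionally ``genetic_status``.
    Adds ``class_human``, ``class_mouse`` (up/down/ns, NaN if absent) and
    ``class_combined`` ("<human>-<mouse>", one of the 9 direction pairs,
    or "<dir>-." / ".-<dir>" for species-only loci).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    out = records.copy()
    h = out["lfc_human"].to_numpy(float)
    m = out["lfc_mouse"].to_numpy(float)
    ch = np.where(np.isnan(h), None, _direction(np.nan_to_num(h), tau))
    cm = np.where(np.isnan(m), None, _direction(np.nan_to_num(m), tau))
    out["class_human"] = ch
    out["class_mouse"] = cm
    out["class_combined"] = [
        f"{a if a is not None else '.'}-{b if b is not None else '.'}"
        for a, b in zip(ch, cm)
    ]
    return out


def overlap_enrichment(
    n_universe: int, n_human: int, n_mouse: int, n_overlap: int
) -> float:
    """One-sided (upper tail) hypergeometric p for set overlap.

    P(X >= k) drawing ``n_mouse`` from a universe of ``n_universe``
    containing ``n_human`` successes.
    """
    if n_universe <= 0:
        raise ValueError("empty universe")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_human, n_mouse))


def overlap_enrichment_from_labels(
    classified: pd.DataFrame, direction: str = "up"
) -> dict:
    """Hypergeometric overlap of human-vs-mouse lineage-specific sets.

    Universe = genetically conserved loci with both species classified.
    """
    sub = classified
    if "genetic_status" in classified.columns:
        sub = classified[classified["genetic_status"] == "conserved"]
    sub = sub[sub["class_human"].notna() & sub["class_mouse"].notna()]
    n = len(sub)
    h = sub["class_human"] == direction
    m = sub["class_mouse"] == direction
    k = int((h & m).sum())
    return dict(
        n_universe=n,
        n_human=int(h.sum()),
        n_mouse=int(m.sum()),
        n_overlap=k,
        p=overlap_enrichment(n, int(h.sum()), int(m.sum()), k),
    )


def rank_cutoff_scan(
    lfc_h: Sequence[float],
    lfc_m: Sequence[float],
    ranks: Sequence[int],
    direction: str = "up",
) -> pd.DataFrame:
    """Overlap enrichment of top-k lineage-specific sets across a rank sweep.

    Loci are ranked by fold change per species (descending for "up",
    ascending for "down"); for each cutoff k the overlap of the two top-k
    sets is tested against the hypergeometric null.
    """
    h = np.asarray(lfc_h, float)
    m = np.asarray(lfc_m, float)
    if len(h) != len(m):
        raise ValueError("fold-change vectors must align")
    n = len(h)
    sign = -1 if direction == "up" else 1
    order_h = np.argsort(sign * h, kind="stable")
    order_m = np.argsort(sign * m, kind="stable")
    rows = []
    for k in ranks:
        k = int(min(k, n))
        top_h = set(order_h[:k])
        top_m = set(order_m[:k])
        ov = len(top_h & top_m)
        rows.append(dict(rank=k, overlap=ov, p=overlap_enrichment(n, k, k, ov)))
    return pd.DataFrame(rows)


# -- gene assignment --------------------------------------------------------------


@dataclass
class GeneAssignment:
    """Element -> gene ids; nonempty by the nearest-gene fallback."""

    atlas_id: str
    genes: list[str]
    nearest: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene assignment must be nonempty")


def assign_to_genes(
    elements: pd.DataFrame,
    gene_models: pd.DataFrame,
    window: int = 100_000,
) -> list[GeneAssignment]:
    """All genes whose body lies within ``window`` bp of an element, else nearest.

    ``elements``: atlas_id, chrom, start, end. ``gene_models``: gene,
    chrom, tss, body_start, body_end. The fallback picks the single gene
    with the smallest TSS distance (genome-wide, any chromosome last).
    """
    if len(gene_models) == 0:
        raise ValueError("empty gene model set")
    out = []
    gm_by_chrom = dict(tuple(gene_models.groupby("chrom")))
    for row in elements.itertuples(index=False):
        sub = gm_by_chrom.get(row.chrom)
        genes: list[str] = []
        if sub is not None:
            near = sub[
                (sub["body_start"] <= row.end + window)
                & (sub["body_end"] >= row.start - window)
            ]
            genes = list(near["gene"])
        center = (row.start + row.end) // 2
        if sub is not None and len(sub):
            dist = np.abs(sub["tss"].to_numpy() - center)
            nearest = sub["gene"].iloc[int(np.argmin(dist))]
        else:  # element on a chromosome with no genes: global nearest by TSS
            nearest = gene_models["gene"].iloc[
                int(np.argmin(np.abs(gene_models["tss"].to_numpy() - center)))
            ]
        if not genes:
            genes = [nearest]
        out.append(GeneAssignment(row.atlas_id, genes, nearest))
    return out


# -- expression concordance -------------------------------------------------------


def translate_genes(genes: Sequence[str], homology: Mapping[str, str]) -> list:
    """Human -> mouse gene-id translation; unmapped ids returned as None (reported)."""
    missing = [g for g in genes if g not in homology]
    if missing:
        warnings.warn(
            f"{len(missing)} gene ids absent from homology map (e.g. {missing[:3]})",
            stacklevel=2,
        )
    return [homology.get(g) for g in genes]


def ecdf(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(np.asarray(values, float))
    return pd.DataFrame({"value": v, "cdf": np.arange(1, len(v) + 1) / len(v)})


def expression_concordance(
    class_genes: Mapping[str, Sequence[str]],
    expr_lfc: Mapping[str, float],
    background_genes: Optional[Sequence[str]] = None,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per element class: ECDF of nearby-gene expression fold change + KS test.

    ``class_genes`` maps a class label to the genes its elements were
    assigned to; ``expr_lfc`` maps gene -> expression log2 fold change in
    one species. Each class is compared to the background gene set
    (default: all genes in ``expr_lfc``) by two-sample KS. Classes with
    fewer than ``min_genes`` genes report the curve but skip the test.
    """
    if background_genes is None:
        background_genes = list(expr_lfc)
    bg = np.array([expr_lfc[g] for g in background_genes if g in expr_lfc])
    rows = []
    for label, genes in class_genes.items():
        vals = np.array([expr_lfc[g] for g in genes if g in expr_lfc])
        if len(vals) < min_genes:
            warnings.warn(
                f"class {label!r} has {len(vals)} genes; KS test skipped",
                stacklevel=2,
            )
            d = p = np.nan
        else:
            d, p = stats.ks_2samp(vals, bg)
        rows.append(
            dict(label=label, n_genes=len(vals), ks_d=d, ks_p=p,
                 median_lfc=float(np.median(vals)) if len(vals) else np.nan)
        )
    return pd.DataFrame(rows)


# -- mobility / functional homology ----------------------------------------------


def mobility_analysis(
    elements: pd.DataFrame,
    expr_h: Mapping[str, float],
    expr_m: Mapping[str, float],
    expr_q_h: Optional[Mapping[str, float]] = None,
    n_perm: int = 1000,
    seed: int = 0,
    weak_lfc: float = 0.5,
    weak_q: float = 0.01,
    activity_floor: float = 1.0,
    top_rank: int = 500,
) -> dict:
    """Functional-homology report for lineage-specific elements.

    ``elements`` needs: atlas_id, genetic_status, class_human, class_mouse,
    gene_human, gene_mouse (assigned genic locus per species, mouse ids
    translated to human space beforehand), lfc_human, lfc_mouse,
    rpm_human, rpm_mouse.

    Three questions are answered:

    1. *Mobility*: genes with a human lineage-specific element and a mouse
       lineage-specific element of the same direction at *different* atlas
       loci; how many have concordant (same-sign, both species)
       expression change? An empirical p permutes expression values over
       genes.
    2. *Inactivation*: lineage-specific elements whose genetically
       conserved ortholog is epigenetically inactive (below
       ``activity_floor`` RPM) in the other species.
    3. *Loosened ranks*: per gene, the maximally lineage-specific element
       per species; genes in the top-``top_rank`` of both species with
       weak differential expression (|lfc| > ``weak_lfc`` or
       q < ``weak_q``).
    """
    rng = np.random.default_rng(seed)
    el = elements

    def ls(col):
        return el[col].isin(["up", "down"])

    # Q1: same gene, same direction, different loci.
    h_ls = el[ls("class_human")]
    m_ls = el[ls("class_mouse")]
    mobile_genes = []
    for gene in sorted(set(h_ls["gene_human"].dropna())):
        h_sub = h_ls[h_ls["gene_human"] == gene]
        m_sub = m_ls[m_ls["gene_mouse"] == gene]
        for d in ("up", "down"):
            h_d = h_sub[h_sub["class_human"] == d]
            m_d = m_sub[m_sub["class_mouse"] == d]
            if len(h_d) and len(m_d):
                # mobile iff some human/mouse element pair sits at
                # different atlas loci
                if len(set(h_d["atlas_id"]) | set(m_d["atlas_id"])) >= 2:
                    mobile_genes.append((gene, d))
                    break

    def concordant(gene: str, d: str) -> bool:
        eh, em = expr_h.get(gene), expr_m.get(gene)
        if eh is None or em is None:
            return False
        s = 1.0 if d == "up" else -1.0
        return s * eh > 0 and s * em > 0

    n_mobile = len(mobile_genes)
    n_concordant = sum(concordant(g, d) for g, d in mobile_genes)
    # Permutation null: shuffle expression across genes, keep element structure.
    genes_all = sorted(set(expr_h) & set(expr_m))
    perm_ge = 0
    if n_mobile and genes_all:
        vals_h = np.array([expr_h[g] for g in genes_all])
        vals_m = np.array([expr_m[g] for g in genes_all])
        for _ in range(n_perm):
            ph = dict(zip(genes_all, vals_h[rng.permutation(len(genes_all))]))
            pm = dict(zip(genes_all, vals_m[rng.permutation(len(genes_all))]))
            cnt = 0
            for g, d in mobile_genes:
                s = 1.0 if d == "up" else -1.0
                if g in ph and g in pm and s * ph[g] > 0 and s * pm[g] > 0:
                    cnt += 1
            perm_ge += cnt >= n_concordant
    p_mobility = (1 + perm_ge) / (n_perm + 1) if n_mobile else np.nan

    # Q2: lineage-specific element, conserved locus, inactive ortholog.
    conserved = el[el["genetic_status"] == "conserved"]
    q2_h = int(
        (
            ls("class_human")
            & (el["genetic_status"] == "conserved")
            & (el["rpm_mouse"] < activity_floor)
        ).sum()
    )
    q2_m = int(
        (
            ls("class_mouse")
            & (el["genetic_status"] == "conserved")
            & (el["rpm_human"] < activity_floor)
        ).sum()
    )

    # Q3: maximally lineage-specific element per gene, loosened rank cutoff.
    per_gene = (
        el.dropna(subset=["gene_human"])
        .groupby("gene_human")
        .agg(max_h=("lfc_human", lambda s: s.abs().max()),
             max_m=("lfc_mouse", lambda s: s.abs().max()))
    )
    per_gene = per_gene.dropna()
    kh = min(top_rank, len(per_gene))
    top_h = set(per_gene["max_h"].nlargest(kh).index)
    top_m = set(per_gene["max_m"].nlargest(kh).index)
    q3_genes = []
    for g in sorted(top_h & top_m):
        eh, eq = expr_h.get(g), (expr_q_h or {}).get(g, 1.0)
        if eh is not None and (abs(eh) > weak_lfc or eq < weak_q):
            q3_genes.append(g)

    return dict(
        mobile_genes=[g for g, _ in mobile_genes],
        n_mobile=n_mobile,
        n_concordant=n_concordant,
        p_mobility=p_mobility,
        n_inactivated_human_ls=q2_h,
        n_inactivated_mouse_ls=q2_m,
        q3_genes=q3_genes,
        n_q3=len(q3_genes),
    )
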