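"""Polymorphism census over DNase hypersensitive sites and the
MAF-constraint permutation test.

For each DHS a narrow window around its center is searched for catalogued
SNPs and the maximum minor allele frequency across the 1000G populations
is recorded and binned. Constraint is tested by comparing how fast the
count of DHSs exceeding each MAF bin decays for genetically conserved vs
non-conserved DHSs: a linear fit of log10(exceed count) on bin value per
group gives a decay steepness, and the conserved-minus-nonconserved
steepness difference is referred to a permutation null obtained by
shuffling the conservation labels.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Bin labels and their left edges: <0.05 -> 0, [0.05,0.15) -> 0.1, ...,
#: >=0.45 -> 0.5 (upper bins are left-closed).
MAF_BIN_LABELS = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
_MAF_EDGES = np.array([0.05, 0.15, 0.25, 0.35, 0.45])


def maf_bin(maf) -> np.ndarray:
    """Bin minor allele frequencies onto the labels {0, 0.1, ..., 0.5}."""
    m = np.asarray(maf, dtype=float)
    if np.any((m < 0) | (m > 0.5)):
        raise ValueError("MAF must be within [0, 0.5]")
    idx = np.digitize(m, _MAF_EDGES, right=False)
    out = MAF_BIN_LABELS[idx]
    return out if out.shape else float(out)


def window_census(
    dhs: pd.DataFrame,
    snps: pd.DataFrame,
    window: int = 150,
    pop_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-DHS SNP count and max MAF in a centered window.

    The window is ``[center - window/2, center + window/2)`` (half-open);
    a DHS with no contained SNP gets max MAF 0. ``snps`` needs chrom, pos
    and per-population MAF columns (default: every column starting with
    ``maf_``).
    """
    if window % 2:
        raise ValueError("window must be even")
    half = window // 2
    if pop_cols is None:
        pop_cols = [c for c in snps.columns if c.startswith("maf_")]
    out = dhs.reset_index(drop=True).copy()
    out["n_snps"] = 0
    out["max_maf"] = 0.0
    centers = ((out["start"] + out["end"]) // 2).to_numpy(np.int64)
    for chrom, sub in snps.groupby("chrom"):
        sel = np.flatnonzero((out["chrom"] == chrom).to_numpy())
        if len(sel) == 0:
            continue
        order = np.argsort(sub["pos"].to_numpy())
        pos = sub["pos"].to_numpy()[order]
        maf = sub[list(pop_cols)].to_numpy(float).max(axis=1)[order]
        lo = np.searchsorted(pos, centers[sel] - half, side="left")
        hi = np.searchsorted(pos, centers[sel] + half, side="left")
        out.loc[sel, "n_snps"] = hi - lo
        mx = np.zeros(len(sel))
        for k, (l, h) in enumerate(zip(lo, hi)):
            if h > l:
                mx[k] = maf[l:h].max()
        out.loc[sel, "max_maf"] = mx
    out["maf_bin"] = maf_bin(out["max_maf"].to_numpy())
    return out


def exceed_counts(bin_values: np.ndarray) -> np.ndarray:
    """Count of DHSs whose max-MAF bin is >= each bin label (nonincreasing)."""
    idx = np.searchsorted(MAF_BIN_LABELS, np.asarray(bin_values) - 1e-9)
    counts = np.bincount(idx, minlength=len(MAF_BIN_LABELS))
    return counts[::-1].cumsum()[::-1]


def decay_steepness(bin_values: np.ndarray) -> float:
    """Steepness of the MAF-spectrum decay: -slope of log10(exceed) on bin value.

    Bins with zero exceed count are dropped from the fit; at least two
    informative bins are required (else NaN).
    """
    idx = np.searchsorted(MAF_BIN_LABELS, np.asarray(bin_values) - 1e-9)
    return _steepness_from_idx(idx)


@dataclass
class ConstraintTestResult:
    steepness_conserved: float
    steepness_nonconserved: float
    delta: float          # conserved minus non-conserved decay steepness
    p_value: float        # add-one permutation convention
    n_perm: int


def constraint_permutation_test(
    summaries: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> ConstraintTestResult:
    """Permutation test for reduced polymorphism at conserved DHSs.

    ``summaries`` needs ``conserved`` (bool) and ``max_maf``. The observed
    statistic is the difference in MAF-spectrum decay steepness between
    conserved and non-conserved DHSs; the null permutes the conservation
    labels (group sizes preserved). p = (1 + #{delta_perm >= delta_obs})
    / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    cons = summaries["conserved"].to_numpy(bool)
    if cons.all() or not cons.any():
        raise ValueError("both conserved and non-conserved DHSs are required")
    bins = maf_bin(summaries["max_maf"].to_numpy())
    idx = np.searchsorted(MAF_BIN_LABELS, bins - 1e-9)

    def delta_of(mask: np.ndarray) -> float:
        return _steepness_from_idx(idx[mask]) - _steepness_from_idx(idx[~mask])

    d_obs = delta_of(cons)
    rng = np.random.default_rng(seed)
    n = len(cons)
    k = int(cons.sum())
    count_ge = 0
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        if delta_of(perm) >= d_obs:
            count_ge += 1
    return ConstraintTestResult(
        steepness_conserved=_steepness_from_idx(idx[cons]),
        steepness_nonconserved=_steepness_from_idx(idx[~cons]),
        delta=d_obs,
        p_value=(1 + count_ge) / (n_perm + 1),
        n_perm=n_perm,
    )


def _steepness_from_idx(bin_idx: np.ndarray) -> float:
    counts = np.bincount(bin_idx, minlength=len(MAF_BIN_LABELS))
    ex = counts[::-1].cumsum()[::-1]
    mask = ex > 0
    if mask.sum() < 2:
        return np.nan
    x = MAF_BIN_LABELS[mask]
    y = np.log10(ex[mask])
    xm, ym = x - x.mean(), y - y.mean()
    return -float((xm * ym).sum() / (xm * xm).sum())


def stratified_census(
    summaries: pd.DataFrame, annotation: pd.Series
) -> pd.DataFrame:
    """Exceed-count curves per genomic category x conservation status.

    ``annotation`` labels each DHS (promoter/exon/intron/distal). Rows:
    category, conserved, bin, count.
    """
    if len(annotation) != len(summaries):
        raise ValueError("annotation must align with summaries")
    rows = []
    df = summaries.assign(category=np.asarray(annotation))
    for (cat, cons), sub in df.groupby(["category", "conserved"], observed=True):
        ex = exceed_counts(maf_bin(sub["max_maf"].to_numpy()))
        for b, c in zip(MAF_BIN_LABELS, ex):
            rows.append(dict(category=cat, conserved=cons, bin=b, count=int(c)))
    return pd.DataFrame(rows)
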