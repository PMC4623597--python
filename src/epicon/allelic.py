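"""Allele-specific histone-modification calling.

Per heterozygous variant, imbalance of ChIP reads over the two alleles is
tested against an exact two-tailed binomial at ratio 0.5. Variants inside
a regulatory element are reduced to LD-independent representatives,
weak-evidence variants (p > 0.2) are discarded, and the remainder are
aggregated per element with Fisher's method (-2 sum ln p). Element-level
significance is an empirical (Monte Carlo) p against a null that mirrors
the observed procedure; a convenience aggregator against the idealised
continuous-uniform null (whose large-sample limit is the chi-square tail
with 2k degrees of freedom) is also provided.

Zygosity-normalised genotype association across heterozygous *and*
homozygous individuals completes the module: doubled heterozygous RPMs,
mean normalisation, a p-value product across the independent het/hom
assessments, and OLS on the {0,1,2,3} allele-code domain.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PREFILTER_CUTOFF = 0.2
INPUT_IMBALANCE_ALPHA = 0.05


# -- read dedup -------------------------------------------------------------------


def dedup_random(reads: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep one read, chosen uniformly at random, per (chrom, start, strand).

    Random selection avoids the reference-alignment bias of score-based
    duplicate removal. Deterministic for a given seed; output preserves
    the input row order of the survivors.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    shuffled = reads.iloc[order]
    kept = shuffled.drop_duplicates(subset=["chrom", "start", "strand"], keep="first")
    return kept.sort_index()


# -- per-variant binomial test ----------------------------------------------------


def binom_two_tailed(ref_n: int, alt_n: int) -> float:
    """Exact two-tailed binomial p at ratio 0.5 (minlike convention).

    At p0 = 0.5 the minlike two-sided p coincides with doubling the
    smaller tail, capped at 1.
    """
    n = ref_n + alt_n
    if n <= 0:
        raise ValueError("zero total depth")
    return float(stats.binomtest(ref_n, n, 0.5).pvalue)


def binom_two_tailed_vec(ref_n: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Vectorized counterpart of :func:`binom_two_tailed`."""
    x = np.asarray(ref_n, dtype=np.int64)
    n = np.asarray(total, dtype=np.int64)
    if np.any(n <= 0):
        raise ValueError("zero total depth")
    lower = stats.binom.cdf(x, n, 0.5)
    upper = stats.binom.sf(x - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def prefilter_snps(pvals: pd.Series, cutoff: float = PREFILTER_CUTOFF) -> pd.Series:
    """Drop variants with p > cutoff: they carry little imbalance evidence.

    The boundary is inclusive (p == cutoff is retained).
    """
    return pvals[pvals <= cutoff]


# -- genotype / het-SNP filters ---------------------------------------------------


def filter_het_snps(
    calls: pd.DataFrame,
    input_depths: pd.DataFrame,
    alpha: float = INPUT_IMBALANCE_ALPHA,
) -> pd.DataFrame:
    """Variants usable for allele-specific testing.

    ``calls``: donor, variant, genotype in {hom-ref, het, hom-alt},
    pass_qc. ``input_depths``: variant, ref, alt (non-ChIPed chromatin,
    summed over donors). A variant is retained when every call passes QC,
    it is heterozygous in >= 2 donors, homozygous in >= 2 donors, and its
    input DNA shows no allelic imbalance (two-tailed binomial p >= alpha).
    Variants with no input record are dropped with a warning.
    """
    inp = input_depths.set_index("variant")
    rows = []
    for variant, sub in calls.groupby("variant"):
        if not sub["pass_qc"].all():
            continue
        n_het = int((sub["genotype"] == "het").sum())
        n_hom = int(sub["genotype"].isin(["hom-ref", "hom-alt"]).sum())
        if n_het < 2 or n_hom < 2:
            continue
        if variant not in inp.index:
            warnings.warn(
                f"variant {variant!r} lacks an input-depth record; dropped",
                stacklevel=2,
            )
            continue
        ref, alt = int(inp.loc[variant, "ref"]), int(inp.loc[variant, "alt"])
        if ref + alt > 0 and binom_two_tailed(ref, alt) < alpha:
            continue
        rows.append(dict(variant=variant, n_het=n_het, n_hom=n_hom))
    return pd.DataFrame(rows, columns=["variant", "n_het", "n_hom"])


# -- LD collapse ------------------------------------------------------------------


def haplotype_r2(h1: np.ndarray, h2: np.ndarray) -> float:
    """LD r^2 between two 0/1 haplotype vectors: D^2 / (p1 q1 p2 q2)."""
    h1 = np.asarray(h1, float)
    h2 = np.asarray(h2, float)
    p1, p2 = h1.mean(), h2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return 0.0
    d = (h1 * h2).mean() - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))


def ld_collapse(
    variants: pd.DataFrame,
    panel: Mapping[str, pd.DataFrame],
    r2_threshold: float = 0.99,
) -> pd.DataFrame:
    """Collapse LD-linked variants within an element to one representative.

    ``variants``: variant, element, depth. ``panel`` maps population name
    to a variants x haplotypes 0/1 frame (index: variant ids). Two
    variants collapse when r^2 > threshold in *all* populations; the
    representative of a linked group is the highest-depth variant (ties:
    lowest variant id). Variants absent from the panel are treated as
    independent, with a warning.
    """
    out_rows = []
    for element, sub in variants.groupby("element"):
        vids = list(sub["variant"])
        parent = {v: v for v in vids}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for i, v1 in enumerate(vids):
            for v2 in vids[i + 1:]:
                linked = True
                for pop, mat in panel.items():
                    if v1 not in mat.index or v2 not in mat.index:
                        warnings.warn(
                            f"variant {v1 if v1 not in mat.index else v2!r} absent "
                            f"from {pop} panel; treated as independent",
                            stacklevel=2,
                        )
                        linked = False
                        break
                    if (
                        haplotype_r2(mat.loc[v1].to_numpy(), mat.loc[v2].to_numpy())
                        <= r2_threshold
                    ):
                        linked = False
                        break
                if linked:
                    parent[find(v1)] = find(v2)
        groups: dict[str, list] = {}
        for v in vids:
            groups.setdefault(find(v), []).append(v)
        depth = dict(zip(sub["variant"], sub["depth"]))
        for members in groups.values():
            rep = sorted(members, key=lambda v: (-depth[v], v))[0]
            out_rows.append(
                dict(element=element, variant=rep, n_collapsed=len(members))
            )
    return pd.DataFrame(out_rows, columns=["element", "variant", "n_collapsed"])


# -- element aggregation ----------------------------------------------------------


def fisher_statistic(pvals: np.ndarray) -> float:
    """Fisher's combination: -2 sum ln p (p = 0 clamped, with warning)."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p <= 0):
        warnings.warn("p = 0 input clamped to smallest positive float", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    return float(-2.0 * np.log(p).sum())


@dataclass
class ElementASEResult:
    element: str
    variants: list
    statistic: float
    empirical_p: float
    n_null: int

    def __post_init__(self) -> None:
        if not (0 < self.empirical_p <= 1):
            raise ValueError("empirical p must lie in (0, 1]")


def aggregate_element(
    pvals: Sequence[float],
    n_null: int = 10_000,
    seed: int = 0,
    element: str = "element",
    variants: Optional[Sequence] = None,
    p_cap: Optional[float] = None,
) -> ElementASEResult:
    """Fisher-aggregate per-variant p-values against a uniform-draw null.

    The null statistic aggregates k draws from Uniform(0, 1) (or
    Uniform(0, p_cap] when the inputs passed an evidence prefilter at
    ``p_cap``), where k is the number of contributing variants; the
    empirical p uses the add-one convention. As n_null grows this
    converges to the chi-square survival function with 2k degrees of
    freedom (for the uncapped null).
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("need >= 1 p-value")
    stat = fisher_statistic(p)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(size=(n_null, len(p)))
    if p_cap is not None:
        draws = draws * p_cap
    null = -2.0 * np.log(draws).sum(axis=1)
    emp = (1 + int((null >= stat).sum())) / (n_null + 1)
    return ElementASEResult(
        element=element,
        variants=list(variants) if variants is not None else list(range(len(p))),
        statistic=stat,
        empirical_p=emp,
        n_null=n_null,
    )


def element_empirical_p(
    ref_counts: np.ndarray,
    depths: np.ndarray,
    n_null: int = 10_000,
    seed: int = 0,
    p_cap: float = PREFILTER_CUTOFF,
) -> tuple[float, float]:
    """Element-level empirical p with a depth-matched parametric null.

    The observed statistic Fisher-aggregates the two-tailed binomial
    p-values of the element's candidate variants that pass the evidence
    prefilter (p <= p_cap). Null replicates redraw each variant's ref
    count as Binomial(depth, 0.5), apply the identical p-value and
    prefilter, and aggregate the survivors; replicates where no variant
    survives are discarded (the element would not have been tested).
    Because the binomial p-values are discrete, ties between observed and
    null statistics carry real mass: they are split uniformly at random,
    which makes the empirical p exactly uniform for a null element.

    Returns (statistic, empirical_p); statistic is NaN when no observed
    variant passes the prefilter.
    """
    ref = np.asarray(ref_counts, np.int64)
    dep = np.asarray(depths, np.int64)
    obs_p = binom_two_tailed_vec(ref, dep)
    keep = obs_p <= p_cap
    if not keep.any():
        return float("nan"), float("nan")
    stat = fisher_statistic(obs_p[keep])

    rng = np.random.default_rng(seed)
    draws = rng.binomial(dep[None, :], 0.5, size=(n_null, len(dep)))
    null_p = binom_two_tailed_vec(draws, np.broadcast_to(dep, draws.shape))
    mask = null_p <= p_cap
    with np.errstate(divide="ignore"):
        terms = np.where(mask, -2.0 * np.log(null_p), 0.0)
    null_stats = terms.sum(axis=1)
    tested = mask.any(axis=1)
    null_stats = null_stats[tested]
    b = len(null_stats)
    if b == 0:
        return stat, 1.0
    greater = int((null_stats > stat + 1e-9).sum())
    tied = int((np.abs(null_stats - stat) <= 1e-9).sum())
    u = rng.uniform()
    emp = (greater + u * (1 + tied)) / (b + 1)
    return stat, float(min(max(emp, np.nextafter(0, 1)), 1.0))


def ase_pipeline(
    genotypes: pd.DataFrame,
    chip_depths: pd.DataFrame,
    input_depths: pd.DataFrame,
    panel: Optional[Mapping[str, pd.DataFrame]] = None,
    n_null: int = 10_000,
    seed: int = 0,
    p_cap: float = PREFILTER_CUTOFF,
) -> pd.DataFrame:
    """Full element-level allele-specificity calling.

    Stages: heterozygous-SNP filtering (QC, >=2 het and >=2 hom donors,
    balanced input), per-variant ChIP depths summed over het donors, LD
    collapse to independent representatives, then per element the exact
    binomial p-values, the p <= 0.2 evidence prefilter and the
    depth-matched empirical aggregation of :func:`element_empirical_p`.

    Returns one row per element with >=1 candidate variant: element,
    n_variants (candidates after collapse), statistic, empirical_p
    (NaN when no variant passed the prefilter, i.e. untested).
    """
    rng = np.random.default_rng(seed)
    usable = filter_het_snps(genotypes, input_depths)
    if len(usable) == 0:
        return pd.DataFrame(
            columns=["element", "n_variants", "statistic", "empirical_p"]
        )
    depths = (
        chip_depths[chip_depths["variant"].isin(usable["variant"])]
        .groupby(["element", "variant"])[["ref", "alt"]]
        .sum()
        .reset_index()
    )
    depths["depth"] = depths["ref"] + depths["alt"]
    depths = depths[depths["depth"] > 0]
    if panel is not None:
        reps = ld_collapse(depths[["variant", "element", "depth"]], panel)
        depths = depths.merge(reps[["element", "variant"]],
                              on=["element", "variant"])
    rows = []
    for element, sub in depths.groupby("element"):
        stat, emp = element_empirical_p(
            sub["ref"].to_numpy(), sub["depth"].to_numpy(),
            n_null=n_null, seed=int(rng.integers(2**31)), p_cap=p_cap,
        )
        rows.append(dict(element=element, n_variants=len(sub),
                         statistic=stat, empirical_p=emp))
    return pd.DataFrame(rows)


def qq_summary(element_pvals: Sequence[float], cap: float = 5.0) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot; observed capped for display."""
    p = np.sort(np.asarray(element_pvals, dtype=float))
    n = len(p)
    expected = -np.log10(np.arange(1, n + 1) / (n + 1))
    observed = np.minimum(-np.log10(p), cap)
    return pd.DataFrame({"expected": expected, "observed": observed})


# -- zygosity-normalised genotype association -------------------------------------


def zygosity_normalize(
    table: pd.DataFrame, min_reads: int = 5
) -> pd.DataFrame:
    """Make het and hom read-coverage RPMs comparable across individuals.

    ``table``: individual, genotype (het / hom-ref / hom-alt), value
    (per-allele RPM for het rows, total RPM for hom rows), n_reads.
    Individuals with ``n_reads <= min_reads`` are excluded ("more than 5
    reads"); heterozygous values are doubled, then everything is divided
    by the dataset mean.
    """
    sub = table[table["n_reads"] > min_reads].copy()
    if len(sub) == 0:
        raise ValueError("all individuals excluded by the read-depth floor")
    sub["normalized"] = np.where(
        sub["genotype"] == "het", 2.0 * sub["value"], sub["value"]
    )
    sub["normalized"] /= sub["normalized"].mean()
    return sub


def combined_zygosity_test(
    p_het: Optional[float], p_hom: Optional[float]
) -> dict:
    """Product of the independent het and hom assessments.

    Heterozygous evidence comes from the within-individual imbalance test,
    homozygous evidence from a two-sample t across genotype groups; the
    individuals are disjoint so the p-values multiply. A missing side is
    reported alone and flagged.
    """
    if p_het is None and p_hom is None:
        raise ValueError("at least one component p-value is required")
    if p_het is None or p_hom is None:
        return dict(p=p_het if p_hom is None else p_hom, complete=False)
    return dict(p=p_het * p_hom, complete=True)


def hom_group_ttest(values_ref: Sequence[float], values_alt: Sequence[float]) -> float:
    """Two-sample t across hom-ref vs hom-alt normalised RPMs."""
    t, p = stats.ttest_ind(np.asarray(values_ref, float), np.asarray(values_alt, float))
    return float(p)


def genotype_codes(table: pd.DataFrame) -> pd.DataFrame:
    """Expand individuals onto the {0,1,2,3} regression domain.

    Homozygous individuals contribute one point (code 0 or 3, total
    value); heterozygous individuals contribute their two allelic values
    at codes 1 and 2 (ref allele at 1, alt allele at 2).
    """
    rows = []
    for r in table.itertuples(index=False):
        if r.genotype == "hom-ref":
            rows.append((0.0, r.value))
        elif r.genotype == "hom-alt":
            rows.append((3.0, r.value))
        elif r.genotype == "het":
            rows.append((1.0, r.value_ref))
            rows.append((2.0, r.value_alt))
        else:
            raise ValueError(f"bad genotype {r.genotype!r}")
    return pd.DataFrame(rows, columns=["code", "value"])


def genotype_regression(values: Sequence[float], codes: Sequence[float]) -> dict:
    """OLS of normalised coverage on allele codes; slope, intercept, p."""
    y = np.asarray(values, float)
    x = np.asarray(codes, float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: constant codes")
    res = stats.linregress(x, y)
    return dict(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(x),
    )


def slope_comparison(
    x_a: Sequence[float], y_a: Sequence[float],
    x_b: Sequence[float], y_b: Sequence[float],
) -> dict:
    """Two-tailed t for a slope difference between two fitted groups.

    Each group is fitted by OLS (slope + intercept); the difference is
    referred to a t distribution with n1 + n2 - 4 degrees of freedom.
    """
    ra = stats.linregress(np.asarray(x_a, float), np.asarray(y_a, float))
    rb = stats.linregress(np.asarray(x_b, float), np.asarray(y_b, float))
    df = len(x_a) + len(x_b) - 4
    if df <= 0:
        raise ValueError("not enough points for the slope comparison")
    se = np.hypot(ra.stderr, rb.stderr)
    if se == 0:
        t = 0.0
    else:
        t = (ra.slope - rb.slope) / se
    p = 2 * stats.t.sf(abs(t), df)
    return dict(t=float(t), p=float(p), df=df,
                slope_a=float(ra.slope), slope_b=float(rb.slope))
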