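"""Calibration and planted-truth recovery studies.

Each function runs one self-contained in-silico experiment — generating
synthetic inputs with the :mod:`epicon.sim` generators, pushing them
through the corresponding pipeline stage, and measuring agreement with
ground truth or a known sampling distribution. The analysis drivers, the
test suite and the reproduction script all call these entry points, so
the numbers they report are always recomputed from scratch.
"""
from __future__ import annotations

import io
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import allelic, disease, lineage, variation
from .atlas import build_union_atlas
from .chains import ChainSet, map_interval, map_interval_per_base, write_chain_file
from .conservation import epigenetic_correlation
from .intervals import GenomicInterval
from .orthology import ASSAY_PARAMS, iterative_ortholog_search
from .sim import (
    SimulationConfig,
    simulate_cohort,
    simulate_dhs_summaries,
    simulate_epigenome,
    simulate_genome_pair,
    simulate_gwas_catalog,
)


# -- chain mapping ----------------------------------------------------------------


def chain_mapping_agreement(
    seed: int = 0, n_queries: int = 1000, n_pairs: int = 4
) -> float:
    """Fraction of random queries where block-arithmetic and per-base
    liftOver agree exactly (status and mapped interval).

    Queries run over several random event-sampled assembly pairs
    (assemblies <= 100 kb, <= 10 chains each).
    """
    rng = np.random.default_rng(seed)
    agree = 0
    per_pair = n_queries // n_pairs
    for k in range(n_pairs):
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31)),
            chrom_sizes={"chrA1": 60_000, "chrA2": 40_000},
            insertion_rate=1e-4, deletion_rate=1e-4,
            inversion_rate=3e-5, break_rate=1e-5, event_size_mean=300,
        )
        pair = simulate_genome_pair(cfg)
        cs = ChainSet(pair.chains)
        for _ in range(per_pair):
            chrom = "chrA1" if rng.uniform() < 0.6 else "chrA2"
            length = int(rng.integers(5, 400))
            s = int(rng.integers(0, cfg.chrom_sizes[chrom] - length))
            q = GenomicInterval(chrom, s, s + length)
            a = map_interval(q, cs)
            b = map_interval_per_base(q, cs)
            agree += (a.status, a.mapped) == (b.status, b.mapped)
    return agree / (per_pair * n_pairs)


def orthology_recovery(seed: int = 0) -> float:
    """Fraction of planted sub-window loci recovered with the exact offset.

    For every assay parameter set and every admissible offset k*step, a
    locus is constructed whose only chain-covered bases are one subwindow
    at that offset; recovery requires status ``subinterval`` and the
    planted offset.
    """
    from .chains import Chain, ChainBlock

    total = correct = 0
    for params in ASSAY_PARAMS.values():
        span = params.locus_span
        start = 10_000
        c0 = start + span // 2
        k_max = (span // 2 - params.subwindow // 2) // params.step
        for k in range(-k_max, k_max + 1):
            wc = c0 + k * params.step
            ws = wc - params.subwindow // 2
            chain = Chain(
                1.0, "chr1", 1_000_000, ws, ws + params.subwindow,
                "chrT", 1_000_000, "+", 5000, 5000 + params.subwindow,
                [ChainBlock(params.subwindow)],
            )
            res = iterative_ortholog_search(
                GenomicInterval("chr1", start, start + span), [chain], params
            )
            total += 1
            correct += (
                res.status == "subinterval" and res.offset == k * params.step
            )
    return correct / total


# -- allele-specific calling ------------------------------------------------------


def binomial_null_rejection(
    seed: int = 0, n_variants: int = 10_000, depth: int = 20, alpha: float = 0.05
) -> float:
    """Type-I error of the exact two-tailed binomial at fixed depth."""
    rng = np.random.default_rng(seed)
    ref = rng.binomial(depth, 0.5, size=n_variants)
    p = allelic.binom_two_tailed_vec(ref, np.full(n_variants, depth))
    return float((p < alpha).mean())


def _cohort_elements(n_elements: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": "chrA1",
            "start": np.arange(n_elements) * 5000,
            "end": np.arange(n_elements) * 5000 + 3000,
        }
    )


def ase_null_pvalues(
    seed: int = 0, n_elements: int = 1000, n_null: int = 10_000
) -> np.ndarray:
    """Element-level empirical p-values of the full pipeline on a null cohort.

    All allelic ratios are 0.5; the returned p-values should be uniform.
    """
    cfg = SimulationConfig(seed=seed, ase_fraction=0.0)
    cohort = simulate_cohort(cfg, _cohort_elements(n_elements))
    res = allelic.ase_pipeline(
        cohort.genotypes, cohort.chip_depths, cohort.input_depths,
        cohort.panel, n_null=n_null, seed=seed + 1,
    )
    return res["empirical_p"].dropna().to_numpy()


def ase_power(
    seed: int = 0, n_elements: int = 300, n_null: int = 10_000,
    theta: float = 0.75, depth_mean: float = 30.0, alpha: float = 0.05,
) -> float:
    """Detection power for planted allele-specific elements.

    Every element carries the planted ratio; power is the fraction of
    elements surviving the het/hom filters that reach empirical
    p < alpha.
    """
    cfg = SimulationConfig(
        seed=seed, ase_fraction=1.0, ase_theta=theta, chip_depth_mean=depth_mean
    )
    cohort = simulate_cohort(cfg, _cohort_elements(n_elements))
    res = allelic.ase_pipeline(
        cohort.genotypes, cohort.chip_depths, cohort.input_depths,
        cohort.panel, n_null=n_null, seed=seed + 1,
    )
    tested = res.dropna(subset=["empirical_p"])
    if len(tested) == 0:
        return 0.0
    return float((tested["empirical_p"] < alpha).mean())


def fisher_chi2_deviation(
    seed: int = 0, ks: Sequence[int] = (1, 2, 5), n_null: int = 100_000,
    trials: int = 5,
) -> float:
    """Max |empirical p - chi2(2k) tail| of the uniform-null aggregator."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in ks:
        for t in range(trials):
            p = rng.uniform(size=k)
            res = allelic.aggregate_element(p, n_null=n_null, seed=seed + t)
            exact = stats.chi2.sf(res.statistic, 2 * k)
            worst = max(worst, abs(res.empirical_p - exact))
    return worst


# -- MAF constraint ---------------------------------------------------------------


def maf_constraint_null_rejection(
    seed: int = 0, runs: int = 1000, n_dhs: int = 2000, n_perm: int = 100,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the constraint test under exchangeable labels."""
    rej = 0
    for i in range(runs):
        df = simulate_dhs_summaries(n_dhs, suppression=0.0, seed=seed * 100_000 + i)
        r = variation.constraint_permutation_test(df, n_perm=n_perm, seed=i)
        rej += r.p_value <= alpha
    return rej / runs


def maf_constraint_power(
    seed: int = 0, runs: int = 100, n_dhs: int = 5000, n_perm: int = 200,
    suppression: float = 0.3, alpha: float = 0.05,
) -> float:
    """Detection rate for planted high-MAF suppression at conserved DHSs."""
    det = 0
    for i in range(runs):
        df = simulate_dhs_summaries(
            n_dhs, suppression=suppression, seed=seed * 100_000 + i
        )
        r = variation.constraint_permutation_test(df, n_perm=n_perm, seed=i)
        det += r.p_value < alpha
    return det / runs


# -- exact-test oracles -----------------------------------------------------------


def hypergeom_oracle_deviation(max_universe: int = 15) -> float:
    """Max |hypergeometric overlap p - exhaustive enumeration| over small universes."""
    from itertools import combinations
    from math import comb

    worst = 0.0
    for n_universe in (6, 10, max_universe):
        for n_a in (2, n_universe // 2):
            for n_b in (2, n_universe // 2 + 1):
                for k in range(0, min(n_a, n_b) + 1):
                    # P(overlap >= k) by direct enumeration over draws of B.
                    total = comb(n_universe, n_b)
                    hits = sum(
                        1
                        for draw in combinations(range(n_universe), n_b)
                        if len(set(draw) & set(range(n_a))) >= k
                    )
                    exact = hits / total
                    p = lineage.overlap_enrichment(n_universe, n_a, n_b, k)
                    worst = max(worst, abs(p - exact))
    return worst


def fisher_exact_oracle_deviation(total: int = 40) -> float:
    """Max |Fisher exact p - exhaustive table enumeration| (conditional null)."""
    from math import comb

    worst = 0.0
    for (a, b, c, d) in [(3, 7, 1, 9), (8, 2, 4, 6), (5, 15, 2, 18), (0, 10, 5, 5)]:
        if a + b + c + d > total:
            continue
        row1, col1, n = a + b, a + c, a + b + c + d
        denom = comb(n, col1)
        probs = {}
        for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
            probs[x] = comb(row1, x) * comb(n - row1, col1 - x) / denom
        p_obs = probs[a]
        exact = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        _, p = stats.fisher_exact([[a, b], [c, d]])
        worst = max(worst, abs(p - exact))
    return worst


# -- atlas recovery ---------------------------------------------------------------


def _count_split_pvalue(x: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Two-sided exact binomial p for a pooled-count split (tail doubling)."""
    lower = stats.binom.cdf(x, n, p0)
    upper = stats.binom.sf(x - 1, n, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def atlas_recovery(
    seed: int = 0, n_loci: int = 20_000, tau: float = 1.0, alpha_ls: float = 2e-4
) -> dict:
    """End-to-end planted-class recovery and correlation estimation.

    Simulates the default-composition epigenome, builds the union atlas
    through the chain mapper, classifies lineage specificity from the
    signal matrices, and reports estimated class proportions plus the
    cross-species signal correlation at conserved loci active in both
    species.

    A lineage-specific call requires both the fold-change threshold and
    count support: an exact test of the pooled aTreg-vs-Teff count split
    at ``alpha_ls``, so that weakly covered loci — whose fold changes are
    dominated by sampling noise — do not leak into the lineage-specific
    classes. ``alpha_ls`` is set so the expected number of false calls
    over the atlas (~ n_loci x alpha) stays in the single digits, small
    against the planted class sizes.
    """
    cfg = SimulationConfig(seed=seed, n_loci=n_loci)
    sim = simulate_epigenome(cfg)
    at = build_union_atlas(
        sim.peaks_h, sim.peaks_m, sim.pair.chains, sim.pair.chains_b2a,
        ASSAY_PARAMS["h3k27ac"],
    )
    df = at.to_frame()

    # Recover locus ids from coordinates (peaks are disjoint per species).
    h_by_start = sim.peaks_h.set_index("start")["locus_id"]
    m_by_start = sim.peaks_m.set_index("start")["locus_id"]
    df["locus_h"] = df["human_start"].map(h_by_start)
    df["locus_m"] = df["mouse_start"].map(m_by_start)
    df.loc[~df["human_peak"], "locus_h"] = None
    df.loc[~df["mouse_peak"], "locus_m"] = None
    df["locus_id"] = df["locus_h"].where(df["locus_h"].notna(), df["locus_m"])

    def ct_stats(sig, ct):
        cols = [c for c in sig.rpm.columns if c.startswith(ct)]
        counts = sig.rpm[cols].mul(sig.totals[cols] / 1e6, axis=1)
        return sig.rpm[cols].mean(axis=1), counts.sum(axis=1), len(cols)

    h_treg, h_tc, h_nt = ct_stats(sim.signal_h, "aTreg")
    h_teff, h_ec, h_ne = ct_stats(sim.signal_h, "Teff")
    m_treg, m_tc, m_nt = ct_stats(sim.signal_m, "aTreg")
    m_teff, m_ec, m_ne = ct_stats(sim.signal_m, "Teff")

    lid = df["locus_id"]
    lfc_h = pd.Series(
        lineage.lfc(h_treg.reindex(lid).to_numpy(), h_teff.reindex(lid).to_numpy()),
        index=df.index,
    )
    lfc_m = pd.Series(
        lineage.lfc(m_treg.reindex(lid).to_numpy(), m_teff.reindex(lid).to_numpy()),
        index=df.index,
    )

    def support(tc, ec, nt, ne):
        x = np.round(tc.reindex(lid).to_numpy()).astype(np.int64)
        y = np.round(ec.reindex(lid).to_numpy()).astype(np.int64)
        x = np.nan_to_num(np.where(x < 0, 0, x))
        tot = np.maximum(x + y, 1)
        p = _count_split_pvalue(x, tot, nt / (nt + ne))
        return pd.Series(p, index=df.index)

    sup_h = support(h_tc, h_ec, h_nt, h_ne)
    sup_m = support(m_tc, m_ec, m_nt, m_ne)

    conserved = df["genetic_status"] == "conserved"
    active_both = df["human_peak"] & df["mouse_peak"]
    ls_h = conserved & active_both & (lfc_h.abs() >= tau) & (sup_h < alpha_ls)
    ls_m = conserved & active_both & (lfc_m.abs() >= tau) & (sup_m < alpha_ls)
    n = len(df)
    est = dict(
        n_atlas=n,
        conserved_active=int((conserved & active_both & ~ls_h & ~ls_m).sum()),
        human_only_ls=int((ls_h & ~ls_m).sum()),
        mouse_only_ls=int((ls_m & ~ls_h).sum()),
        both_ls=int(
            (ls_h & ls_m & (np.sign(lfc_h) == np.sign(lfc_m))).sum()
        ),
    )

    sub = df[conserved & active_both].copy()
    sub["rpm_human"] = h_treg.reindex(sub["locus_id"]).to_numpy()
    sub["rpm_mouse"] = m_treg.reindex(sub["locus_id"]).to_numpy()
    r, _ = epigenetic_correlation(sub.assign(genetic_status="conserved"))
    est["correlation"] = r
    est["truth"] = sim.truth.loci["cls"].value_counts().to_dict()
    return est


# -- disease enrichment -----------------------------------------------------------


def disease_enrichment_pvalues(
    seed: int = 0, runs: int = 50, factor: float = 1.0, n_snps: int = 500
) -> np.ndarray:
    """Enrichment p-values over repeated synthetic catalogs.

    With ``factor`` 1 the catalog is unenriched and the p-values should
    be roughly uniform; with a planted factor > 1 they should be small.
    """
    chrom_sizes = {"chrA1": 10_000_000}
    rng = np.random.default_rng(seed)
    elements = pd.DataFrame(
        {"chrom": "chrA1", "start": np.arange(20) * 450_000 + 100_000,
         "end": np.arange(20) * 450_000 + 103_000}
    )
    regions = disease.expand_risk_regions(elements, chrom_sizes=chrom_sizes)
    pvals = []
    target = disease.DiseaseSet(
        "autoimmune",
        ("type 1 diabetes", "rheumatoid arthritis", "celiac disease"),
    )
    for i in range(runs):
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31)), n_catalog_snps=n_snps,
            enrichment_factor={"autoimmune": factor, "metabolic": 1.0,
                               "psychiatric": 1.0},
        )
        catalog, _ = simulate_gwas_catalog(cfg, regions, chrom_sizes)
        catalog = disease.filter_studies(catalog)
        res = disease.enrichment_test(target, catalog, regions)
        pvals.append(res["p"])
    return np.asarray(pvals)


# -- determinism ------------------------------------------------------------------


def determinism_check(seed: int = 0) -> bool:
    """Byte-identical reruns of every stochastic generator at a fixed seed."""
    def render(s: int) -> bytes:
        buf = io.BytesIO()
        cfg = SimulationConfig(seed=s, n_loci=200)
        sim = simulate_epigenome(cfg)
        txt = io.StringIO()
        sim.peaks_h.to_csv(txt, sep="\t", index=False)
        sim.peaks_m.to_csv(txt, sep="\t", index=False)
        sim.signal_h.rpm.to_csv(txt, sep="\t", float_format="%.6g")
        sim.expression_h.to_csv(txt, sep="\t", index=False, float_format="%.6g")
        sim.truth.loci.to_csv(txt, sep="\t", index=False, float_format="%.6g")
        import tempfile, os

        with tempfile.NamedTemporaryFile("w+", suffix=".chain", delete=False) as fh:
            path = fh.name
        write_chain_file(sim.pair.chains, path)
        with open(path) as fh:
            txt.write(fh.read())
        os.unlink(path)
        cohort = simulate_cohort(SimulationConfig(seed=s), _cohort_elements(50))
        cohort.chip_depths.to_csv(txt, sep="\t", index=False)
        cohort.maf_table.to_csv(txt, sep="\t", index=False, float_format="%.6g")
        catalog, _ = simulate_gwas_catalog(
            SimulationConfig(seed=s),
            pd.DataFrame({"chrom": ["chrA1"], "start": [0], "end": [50_000]}),
            {"chrA1": 1_000_000},
        )
        catalog.to_csv(txt, sep="\t", index=False)
        buf.write(txt.getvalue().encode())
        return buf.getvalue()

    return render(seed) == render(seed)
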