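"""Synthetic cross-species epigenomes with planted conservation classes.

Loci are laid out on a locus-anchored assembly pair (one alignment
segment per genetically conserved locus, assembly-specific slots for the
rest), so genetic-conservation truth is exact. Per-locus baseline signal
is bivariate log-normal across species with a configurable correlation;
lineage-specific classes add a symmetric aTreg-vs-Teff fold change in the
corresponding species; counts are negative binomial per sample. Nearby
gene expression changes concordantly with the planted class.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ..signal import SignalMatrix
from .config import SimulationConfig, TruthTable
from .genome import GenomePair, anchored_genome_pair

CLASSES = (
    "conserved_active",
    "human_only_ls",
    "mouse_only_ls",
    "both_ls",
    "discordant",
    "conserved_human_active",
    "conserved_mouse_active",
    "human_only_genetic",
    "mouse_only_genetic",
)

CELL_TYPES = ("aTreg", "rTreg", "Teff", "Tn")


@dataclass
class SyntheticEpigenome:
    pair: GenomePair
    peaks_h: pd.DataFrame
    peaks_m: pd.DataFrame
    signal_h: SignalMatrix
    signal_m: SignalMatrix
    expression_h: pd.DataFrame
    expression_m: pd.DataFrame
    gene_models_h: pd.DataFrame
    gene_models_m: pd.DataFrame
    homology: pd.DataFrame
    truth: TruthTable


def _nb_counts(rng, mean: np.ndarray, size: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, float), 1e-9)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _sample_classes(rng, n: int, proportions) -> np.ndarray:
    names = [c for c in CLASSES if proportions.get(c, 0) > 0]
    probs = np.array([proportions[c] for c in names], dtype=float)
    leftover = 1.0 - probs.sum()
    if leftover > 1e-9:
        names.append("conserved_active")
        probs = np.append(probs, leftover)
    probs = probs / probs.sum()
    return rng.choice(names, size=n, p=probs)


def simulate_epigenome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SyntheticEpigenome:
    """Generate peaks, signal matrices and expression with planted truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_loci
    classes = _sample_classes(rng, n, config.class_proportions)

    human_extra = classes == "human_only_genetic"
    mouse_extra = classes == "mouse_only_genetic"
    conserved = ~(human_extra | mouse_extra)
    pair = anchored_genome_pair(
        n, config.locus_length, config.locus_spacing,
        conserved, human_extra, mouse_extra,
    )

    # Baseline log2 signal, correlated across species.
    mu = np.log2(config.nb_mean)
    cov = (config.log2_signal_sd ** 2) * np.array(
        [[1.0, config.signal_correlation], [config.signal_correlation, 1.0]]
    )
    z = rng.multivariate_normal([mu, mu], cov, size=n)
    base_h, base_m = 2.0 ** z[:, 0], 2.0 ** z[:, 1]

    active_h = ~np.isin(classes, ["conserved_mouse_active", "mouse_only_genetic"])
    active_m = ~np.isin(classes, ["conserved_human_active", "human_only_genetic"])

    # Planted lineage direction: +1 up in aTreg, -1 down, 0 none.
    direction = rng.choice([-1, 1], size=n)
    dir_h = np.where(np.isin(classes, ["human_only_ls", "both_ls", "discordant"]),
                     direction, 0)
    dir_m = np.where(np.isin(classes, ["mouse_only_ls", "both_ls"]), direction, 0)
    dir_m = np.where(classes == "discordant", -direction, dir_m)

    half = np.sqrt(config.fold_effect)

    def cell_type_mean(base, active, d, cell_type):
        m = np.where(active, base, config.background_mean)
        if cell_type in ("aTreg", "rTreg"):
            m = m * np.where(d == 1, half, np.where(d == -1, 1 / half, 1.0))
        else:
            m = m * np.where(d == 1, 1 / half, np.where(d == -1, half, 1.0))
        return m

    def build_matrix(base, active, d, replicates):
        cols = {}
        for ct in CELL_TYPES:
            m = cell_type_mean(base, active, d, ct)
            for r in range(replicates.get(ct, 0)):
                cols[f"{ct}_{r + 1}"] = _nb_counts(rng, m, config.nb_size)
        counts = pd.DataFrame(cols, index=[f"locus{i:05d}" for i in range(n)])
        rpm = counts * (1e6 / config.library_size)
        totals = pd.Series(config.library_size, index=counts.columns)
        return SignalMatrix(rpm=rpm.astype(float), totals=totals)

    signal_h = build_matrix(base_h, active_h, dir_h, config.replicates_human)
    signal_m = build_matrix(base_m, active_m, dir_m, config.replicates_mouse)

    # Peaks exist where the species is epigenetically active.
    starts_a = pair.locus_starts_a
    starts_b = pair.locus_starts_b
    L = config.locus_length

    def peaks_frame(starts, active, chrom):
        sel = (starts >= 0) & active
        idx = np.flatnonzero(sel)
        return pd.DataFrame(
            dict(
                chrom=chrom,
                start=starts[idx],
                end=starts[idx] + L,
                locus_id=[f"locus{i:05d}" for i in idx],
            )
        )

    peaks_h = peaks_frame(starts_a, active_h, "chrA1")
    peaks_m = peaks_frame(starts_b, active_m, "chrB1")

    # Gene models: one gene per locus, TSS just downstream of the locus.
    genes_h = [f"GENE{i:05d}" for i in range(n)]
    genes_m = [f"Gene{i:05d}" for i in range(n)]

    def gene_models(starts, chrom, names):
        sel = starts >= 0
        idx = np.flatnonzero(sel)
        tss = starts[idx] + L + 500
        return pd.DataFrame(
            dict(gene=[names[i] for i in idx], chrom=chrom, tss=tss,
                 body_start=tss, body_end=tss + 10_000, strand="+")
        )

    gene_models_h = gene_models(starts_a, "chrA1", genes_h)
    gene_models_m = gene_models(starts_b, "chrB1", genes_m)
    homology = pd.DataFrame({"human_gene": genes_h, "mouse_gene": genes_m})

    # Expression fold changes concordant with the planted element class.
    drives = rng.uniform(size=n) < config.expr_concordance
    expr_truth_h = np.where(drives, dir_h * config.expr_effect, 0.0)
    expr_truth_m = np.where(drives, dir_m * config.expr_effect, 0.0)

    def expression(names, truth_lfc, starts):
        sel = starts >= 0
        idx = np.flatnonzero(sel)
        obs = truth_lfc[idx] + rng.normal(0, config.expr_noise_sd, size=len(idx))
        pvals = 2 * stats.norm.sf(np.abs(obs) / config.expr_noise_sd)
        qvals = stats.false_discovery_control(pvals)
        return pd.DataFrame(
            dict(gene=[names[i] for i in idx], lfc=obs, q=qvals)
        )

    expression_h = expression(genes_h, expr_truth_h, starts_a)
    expression_m = expression(genes_m, expr_truth_m, starts_b)

    truth = TruthTable(
        loci=pd.DataFrame(
            dict(
                locus_id=[f"locus{i:05d}" for i in range(n)],
                cls=classes,
                direction=direction,
                lfc_human=2.0 * dir_h * np.log2(half),
                lfc_mouse=2.0 * dir_m * np.log2(half),
                active_human=active_h,
                active_mouse=active_m,
                genetically_conserved=conserved,
                base_log2_human=z[:, 0],
                base_log2_mouse=z[:, 1],
            )
        ),
        segments=pair.segments,
    )
    return SyntheticEpigenome(
        pair=pair, peaks_h=peaks_h, peaks_m=peaks_m,
        signal_h=signal_h, signal_m=signal_m,
        expression_h=expression_h, expression_m=expression_m,
        gene_models_h=gene_models_h, gene_models_m=gene_models_m,
        homology=homology, truth=truth,
    )


def simulate_reads(
    peaks: pd.DataFrame,
    counts: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Read-start records realising a per-locus count matrix.

    For each (locus, sample) cell, that many plus-strand read starts are
    placed so the shifted central window falls inside the peak. Intended
    for small, read-level end-to-end runs.
    """
    rows = []
    peak_ix = peaks.set_index("locus_id")
    for locus in counts.index:
        if locus not in peak_ix.index:
            continue
        p = peak_ix.loc[locus]
        for sample in counts.columns:
            k = int(counts.loc[locus, sample])
            if k <= 0:
                continue
            starts = rng.integers(p["start"] - 50, p["end"] - 150, size=k)
            for s in starts:
                rows.append((p["chrom"], int(s), "+", sample))
    return pd.DataFrame(rows, columns=["chrom", "start", "strand", "sample"])
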