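"""Simulation configuration and planted-truth bookkeeping.

Defaults mirror the study design the pipeline targets: the human ChIP
panel has 7 aTreg, 4 rTreg, 2 Teff and 1 Tn samples from 7 donors, the
mouse panel 2 aTreg, 4 rTreg, 2 Teff and 4 Tn biological replicates; the
planted atlas composition is ~85% conserved-active loci, ~1.5%
lineage-specific per single species and ~0.1% lineage-specific in both;
lineage-specific elements change 4-fold between aTreg and Teff. Read
depths are negative binomial with mean 50 and size 50 (dispersion 0.02 —
biological replicates of ChIP signal at active elements correlate at
r > 0.99, i.e. replicate noise is near-Poisson).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

#: Planted locus classes and their default atlas proportions.
DEFAULT_CLASS_PROPORTIONS = {
    "conserved_active": 0.85,
    "human_only_ls": 0.015,
    "mouse_only_ls": 0.015,
    "both_ls": 0.001,
    "discordant": 0.001,
    "conserved_human_active": 0.04,   # genetically conserved, active in human only
    "conserved_mouse_active": 0.04,   # genetically conserved, active in mouse only
    "human_only_genetic": 0.019,      # sequence not conserved
    "mouse_only_genetic": 0.019,
}

DEFAULT_REPLICATES_HUMAN = {"aTreg": 7, "rTreg": 4, "Teff": 2, "Tn": 1}
DEFAULT_REPLICATES_MOUSE = {"aTreg": 2, "rTreg": 4, "Teff": 2, "Tn": 4}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated conditions."""

    seed: int = 0

    # genome pair
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chrA1": 1_000_000}
    )
    insertion_rate: float = 2e-5     # events per bp
    deletion_rate: float = 2e-5
    inversion_rate: float = 5e-6
    break_rate: float = 2e-6
    event_size_mean: float = 800.0   # geometric mean length of indel/inversion events

    # epigenome
    n_loci: int = 2_000
    locus_length: int = 3_000
    locus_spacing: int = 2_000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    fold_effect: float = 4.0
    nb_mean: float = 50.0
    nb_size: float = 50.0            # NB size parameter; dispersion = 1/size
    log2_signal_sd: float = 2.0      # dynamic range of per-locus baseline signal
    signal_correlation: float = 0.5  # cross-species correlation of log baselines
    background_mean: float = 0.5     # counts at epigenetically inactive loci
    replicates_human: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES_HUMAN)
    )
    replicates_mouse: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES_MOUSE)
    )
    library_size: int = 1_000_000
    expr_effect: float = 2.0         # expression lfc magnitude near LS loci
    expr_noise_sd: float = 0.4
    expr_concordance: float = 1.0    # prob. a LS locus drives its gene's expression

    # cohort / allele-specific
    n_donors: int = 7
    ase_fraction: float = 0.1
    ase_theta: float = 0.75
    chip_depth_mean: float = 30.0
    input_depth_mean: float = 30.0
    variants_per_element: float = 3.0
    maf_beta_a: float = 0.8
    maf_beta_b: float = 3.0
    panel_haplotypes: int = 100
    ld_block_size: int = 2          # variants per perfectly linked block

    # GWAS catalog
    n_catalog_snps: int = 500
    snps_per_study_mean: float = 8.0
    enrichment_factor: Mapping[str, float] = field(
        default_factory=lambda: {"autoimmune": 5.0, "metabolic": 1.0,
                                 "psychiatric": 1.0}
    )

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"class proportions sum to {total} > 1")
        if not (0.5 < self.ase_theta < 1):
            raise ValueError("ase_theta must lie in (0.5, 1)")
        for name in ("insertion_rate", "deletion_rate", "inversion_rate",
                     "break_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for c, s in self.chrom_sizes.items():
            if s <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length")


@dataclass
class TruthTable:
    """Planted ground truth emitted alongside every synthetic dataset."""

    loci: Optional[pd.DataFrame] = None       # locus id, class, per-species truth
    variants: Optional[pd.DataFrame] = None   # variant id, planted allelic ratio
    catalog: Optional[pd.DataFrame] = None    # trait, enriched flag per variant
    segments: Optional[pd.DataFrame] = None   # chain ground-truth base map
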