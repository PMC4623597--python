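"""Synthetic GWAS catalogs with planted trait enrichment.

Background variants fall uniformly over the assembly; for a disease set
with enrichment factor > 1, variants land inside the target regions with
that multiple of the chance probability. Study sizes straddle the
">5 independent SNPs" inclusion filter so it is exercised downstream.
"""
from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig, TruthTable

TRAITS_PER_SET = {
    "autoimmune": ("type 1 diabetes", "rheumatoid arthritis", "celiac disease"),
    "metabolic": ("type 2 diabetes", "obesity"),
    "psychiatric": ("schizophrenia", "bipolar disorder"),
}


def simulate_gwas_catalog(
    config: SimulationConfig,
    regions: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Catalog TSV frame (variant, chrom, pos, trait, study) + truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    total_len = lengths.sum()
    region_len = float((regions["end"] - regions["start"]).sum())
    base_p = region_len / total_len

    sets = list(config.enrichment_factor)
    rows = []
    vidx = 0
    study_idx = 0
    reg_by_chrom = {c: sub for c, sub in regions.groupby("chrom")}

    def draw_pos(inside: bool):
        if inside:
            weights = (regions["end"] - regions["start"]).to_numpy(float)
            i = rng.choice(len(regions), p=weights / weights.sum())
            row = regions.iloc[i]
            return row["chrom"], int(rng.integers(row["start"], row["end"]))
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        return chrom, int(rng.integers(0, chrom_sizes[chrom]))

    n_per_set = config.n_catalog_snps // len(sets)
    for set_name in sets:
        factor = config.enrichment_factor[set_name]
        p_in = min(0.95, factor * base_p)
        traits = TRAITS_PER_SET.get(set_name, (set_name,))
        remaining = n_per_set
        while remaining > 0:
            # Study sizes straddle the >5-SNP filter (some exactly 5).
            size = int(
                min(remaining, max(3, rng.poisson(config.snps_per_study_mean)))
            )
            study_idx += 1
            study = f"GCST{study_idx:05d}"
            trait = traits[study_idx % len(traits)]
            for _ in range(size):
                inside = bool(rng.uniform() < p_in)
                chrom, pos = draw_pos(inside)
                rows.append(
                    dict(variant=f"gwas_rs{vidx:06d}", chrom=chrom, pos=pos,
                         trait=trait, study=study, disease_set=set_name,
                         planted_inside=inside)
                )
                vidx += 1
            remaining -= size
    catalog = pd.DataFrame(rows)
    truth = TruthTable(catalog=catalog[["variant", "disease_set",
                                        "planted_inside"]].copy())
    return catalog.drop(columns=["planted_inside"]), truth
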