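"""Synthetic donor cohorts with planted allele-specific acetylation.

Each regulatory element receives a handful of common variants; donors are
genotyped under Hardy-Weinberg at population allele frequencies. At
planted allele-specific elements, heterozygous donors' ChIP reads favour
the reference allele with probability theta; everywhere else (and in all
input chromatin) reads split 50/50. Panel haplotypes carry configurable
perfect-LD blocks so the r^2 collapse step has real work to do.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig, TruthTable


@dataclass
class SyntheticCohort:
    genotypes: pd.DataFrame       # donor, variant, genotype, pass_qc
    chip_depths: pd.DataFrame     # donor, variant, element, ref, alt
    input_depths: pd.DataFrame    # variant, ref, alt (summed over donors)
    panel: dict                   # population -> variants x haplotypes 0/1
    maf_table: pd.DataFrame       # variant, chrom, pos, maf_<pop> ...
    variants: pd.DataFrame        # variant, element, chrom, pos, theta
    truth: TruthTable


POPULATIONS = ("afr", "eur", "ceu", "chb", "jpt")


def simulate_cohort(
    config: SimulationConfig,
    elements: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticCohort:
    """Genotypes, allelic depths and panel haplotypes for a donor cohort.

    ``elements`` is a BED-like frame (chrom, start, end and optionally
    locus_id) of regulatory elements to seed with variants.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    elements = elements.reset_index(drop=True)
    el_ids = (
        elements["locus_id"].tolist()
        if "locus_id" in elements.columns
        else [f"element{i:05d}" for i in range(len(elements))]
    )

    var_rows = []
    vidx = 0
    ase_elements = rng.uniform(size=len(elements)) < config.ase_fraction
    for i, el in enumerate(elements.itertuples(index=False)):
        k = max(1, rng.poisson(config.variants_per_element))
        positions = np.sort(
            rng.choice(np.arange(el.start, el.end), size=k, replace=False)
        )
        theta = config.ase_theta if ase_elements[i] else 0.5
        for pos in positions:
            var_rows.append(
                dict(
                    variant=f"rs{vidx:07d}", element=el_ids[i],
                    chrom=el.chrom, pos=int(pos), theta=theta,
                )
            )
            vidx += 1
    variants = pd.DataFrame(var_rows)
    nv = len(variants)

    # Population allele frequencies (folded to minor) per variant.
    maf = {
        f"maf_{p}": np.minimum(
            rng.beta(config.maf_beta_a, config.maf_beta_b, size=nv), 0.5
        )
        for p in POPULATIONS
    }
    maf_table = pd.DataFrame(dict(variant=variants["variant"],
                                  chrom=variants["chrom"],
                                  pos=variants["pos"], **maf))

    # Donor genotypes (HWE at the mean frequency across populations).
    freqs = np.column_stack([maf[f"maf_{p}"] for p in POPULATIONS]).mean(axis=1)
    donors = [f"D{d + 1:03d}" for d in range(config.n_donors)]
    geno_rows, chip_rows = [], []
    input_ref = np.zeros(nv, dtype=np.int64)
    input_alt = np.zeros(nv, dtype=np.int64)
    for j, var in enumerate(variants.itertuples(index=False)):
        f = freqs[j]
        for donor in donors:
            alleles = rng.uniform(size=2) < f
            gt = ("hom-ref", "het", "hom-alt")[int(alleles.sum())]
            geno_rows.append(dict(donor=donor, variant=var.variant,
                                  genotype=gt, pass_qc=True))
            depth = rng.poisson(config.chip_depth_mean)
            idepth = rng.poisson(config.input_depth_mean)
            if gt == "het":
                ref = rng.binomial(depth, var.theta) if depth else 0
                iref = rng.binomial(idepth, 0.5) if idepth else 0
                chip_rows.append(
                    dict(donor=donor, variant=var.variant, element=var.element,
                         ref=int(ref), alt=int(depth - ref))
                )
                input_ref[j] += iref
                input_alt[j] += idepth - iref
    genotypes = pd.DataFrame(geno_rows)
    chip_depths = pd.DataFrame(
        chip_rows, columns=["donor", "variant", "element", "ref", "alt"]
    )
    input_depths = pd.DataFrame(
        dict(variant=variants["variant"], ref=input_ref, alt=input_alt)
    )

    # Panel haplotypes with perfect-LD blocks of ld_block_size variants.
    panel = {}
    n_hap = config.panel_haplotypes
    block = np.arange(nv) // max(1, config.ld_block_size)
    # Block structure must respect element boundaries.
    el_codes = pd.factorize(variants["element"])[0]
    block = block * (el_codes.max() + 1 if nv else 1) + el_codes
    _, block = np.unique(block, return_inverse=True)
    for p in POPULATIONS:
        f_pop = maf[f"maf_{p}"]
        mat = np.zeros((nv, n_hap), dtype=np.int8)
        for b in np.unique(block):
            members = np.flatnonzero(block == b)
            hap = rng.uniform(size=n_hap) < f_pop[members[0]]
            mat[members] = hap.astype(np.int8)
        panel[p] = pd.DataFrame(mat, index=variants["variant"])

    truth = TruthTable(
        variants=variants.assign(
            ase=[t != 0.5 for t in variants["theta"]]
        )
    )
    return SyntheticCohort(
        genotypes=genotypes, chip_depths=chip_depths, input_depths=input_depths,
        panel=panel, maf_table=maf_table, variants=variants, truth=truth,
    )


def write_vcf(cohort: SyntheticCohort, path) -> None:
    """Minimal VCF 4.2 with GT:AD per donor (text, bgzip-free)."""
    donors = sorted(cohort.genotypes["donor"].unique())
    gt_map = {"hom-ref": "0/0", "het": "0/1", "hom-alt": "1/1"}
    geno = cohort.genotypes.set_index(["variant", "donor"])["genotype"]
    ad = cohort.chip_depths.groupby(["variant", "donor"])[["ref", "alt"]].sum()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        chroms = cohort.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(donors) + "\n"
        )
        for var in cohort.variants.itertuples(index=False):
            cells = []
            for d in donors:
                gt = gt_map[geno.loc[(var.variant, d)]]
                if (var.variant, d) in ad.index:
                    r, a = ad.loc[(var.variant, d)]
                else:
                    r = a = 0
                cells.append(f"{gt}:{int(r)},{int(a)}")
            fh.write(
                f"{var.chrom}\t{var.pos + 1}\t{var.variant}\tA\tG\t.\tPASS\t.\t"
                "GT:AD\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes and allelic depths from a GT:AD VCF via pysam."""
    import pysam

    geno_rows, depth_rows = [], []
    code = {(0, 0): "hom-ref", (0, 1): "het", (1, 0): "het", (1, 1): "hom-alt"}
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch() if vcf.index else vcf:
            for donor, sample in rec.samples.items():
                gt = tuple(sample["GT"])
                geno_rows.append(
                    dict(donor=donor, variant=rec.id, genotype=code[gt],
                         pass_qc="PASS" in rec.filter or len(rec.filter) == 0)
                )
                r, a = sample["AD"]
                depth_rows.append(
                    dict(donor=donor, variant=rec.id, ref=int(r), alt=int(a))
                )
    return pd.DataFrame(geno_rows), pd.DataFrame(depth_rows)
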