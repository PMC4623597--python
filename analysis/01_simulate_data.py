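"""Generate the synthetic cross-species study all downstream drivers analyse.

Writes, under results/synthetic/: the human/mouse peak sets (BED), the
alignment chain file relating the two assemblies, per-cell-type mean RPM
matrices, expression tables, gene models, the donor cohort (VCF +
allelic-depth and MAF tables) and the planted-truth tables.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from common import DATA, SEED, ensure_dirs, study_config
from epicon.chains import write_chain_file
from epicon.io import write_bed, write_table
from epicon.sim import simulate_cohort, simulate_epigenome, write_vcf


def main() -> None:
    ensure_dirs()
    cfg = study_config()
    sim = simulate_epigenome(cfg)

    write_bed(sim.peaks_h, DATA / "peaks_human.bed", cols=("locus_id",))
    write_bed(sim.peaks_m, DATA / "peaks_mouse.bed", cols=("locus_id",))
    write_chain_file(sim.pair.chains, DATA / "human_to_mouse.chain")

    for name, sig in (("human", sim.signal_h), ("mouse", sim.signal_m)):
        by_ct = sig.rpm.T.groupby(
            sig.rpm.columns.str.split("_").str[0]
        ).mean().T
        write_table(by_ct.rename_axis("locus_id"),
                    DATA / f"rpm_{name}.tsv", index=True)
    write_table(sim.expression_h, DATA / "expression_human.tsv")
    write_table(sim.expression_m, DATA / "expression_mouse.tsv")
    write_table(sim.gene_models_h, DATA / "genes_human.tsv")
    write_table(sim.gene_models_m, DATA / "genes_mouse.tsv")
    write_table(sim.homology, DATA / "homology.tsv")
    write_table(sim.truth.loci, DATA / "truth_loci.tsv")

    cohort = simulate_cohort(study_config(), sim.peaks_h.head(200))
    write_vcf(cohort, DATA / "cohort.vcf")
    write_table(cohort.chip_depths, DATA / "chip_allelic_depths.tsv")
    write_table(cohort.input_depths, DATA / "input_allelic_depths.tsv")
    write_table(cohort.maf_table, DATA / "maf_populations.tsv")
    write_table(cohort.variants, DATA / "truth_variants.tsv")

    t = sim.truth.loci["cls"].value_counts()
    print(f"simulated {cfg.n_loci} loci (seed {SEED}):")
    print(t.to_string())
    print(f"peaks: {len(sim.peaks_h)} human, {len(sim.peaks_m)} mouse")
    print(f"cohort: {cohort.genotypes['donor'].nunique()} donors, "
          f"{len(cohort.variants)} variants in 200 elements")
    print(f"wrote inputs to {DATA}")


if __name__ == "__main__":
    main()
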