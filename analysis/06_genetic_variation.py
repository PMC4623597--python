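"""Polymorphism census at DHSs and the MAF-constraint permutation test.

Runs the 150 bp window census of synthetic SNPs over DHS centers, bins
maximum population MAFs, and tests whether genetically conserved DHSs
carry fewer high-MAF variants than non-conserved DHSs by permuting the
conservation labels. Writes results/dhs_census.tsv and
results/constraint_test.tsv.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from common import DATA, RESULTS, SEED, ensure_dirs
from epicon.io import read_table, write_table
from epicon.sim import simulate_dhs_summaries
from epicon.variation import (
    constraint_permutation_test,
    stratified_census,
    window_census,
)


def main() -> None:
    ensure_dirs()
    rng = np.random.default_rng(SEED)

    # Window census over the cohort's MAF table and the human peaks as DHSs.
    snps = read_table(DATA / "maf_populations.tsv")
    from epicon.io import read_bed
    dhs = read_bed(DATA / "peaks_human.bed", extra_cols=("locus_id",)).head(200)
    census = window_census(dhs, snps, window=150)
    write_table(census[["locus_id", "chrom", "start", "end", "n_snps",
                        "max_maf", "maf_bin"]], RESULTS / "dhs_census.tsv")
    with_snp = int((census["n_snps"] > 0).sum())
    common = int((census["max_maf"] >= 0.05).sum())
    print(f"window census over {len(census)} DHSs: {with_snp} contain >= 1 "
          f"SNP in the central 150 bp, {common} a common (MAF >= 0.05) one")

    # Constraint test on summary-level DHSs with planted suppression.
    summaries = simulate_dhs_summaries(5000, suppression=0.3, seed=SEED)
    res = constraint_permutation_test(summaries, n_perm=1000, seed=SEED)
    out = pd.DataFrame([{
        "steepness_conserved": res.steepness_conserved,
        "steepness_nonconserved": res.steepness_nonconserved,
        "delta": res.delta, "p": res.p_value, "n_perm": res.n_perm}])
    write_table(out, RESULTS / "constraint_test.tsv")
    print(f"\nMAF-spectrum decay steepness: conserved "
          f"{res.steepness_conserved:.3f} vs non-conserved "
          f"{res.steepness_nonconserved:.3f}; permutation p = "
          f"{res.p_value:.4g} ({res.n_perm} permutations)")

    ann = pd.Series(rng.choice(["promoter", "intron", "distal"],
                               size=len(summaries), p=[0.2, 0.3, 0.5]))
    strat = stratified_census(summaries, ann)
    write_table(strat, RESULTS / "constraint_stratified.tsv")


if __name__ == "__main__":
    main()
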