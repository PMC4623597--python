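"""Quantify genetic and epigenetic conservation over the atlas.

Computes the cross-species correlation of activated-Treg acetylation at
genetically conserved, epigenetically active loci, and the fraction of
genetically conserved loci stratified by signal strength. Writes
results/conservation_correlation.tsv and results/conserved_fractions.tsv.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

from common import DATA, RESULTS, ensure_dirs
from epicon.conservation import (
    conserved_fraction_by_stratum,
    epigenetic_correlation,
    rpm_quantile_strata,
)
from epicon.io import read_bed, read_table, write_table


def main() -> None:
    ensure_dirs()
    rec = read_table(RESULTS / "atlas.tsv")
    rpm_h = read_table(DATA / "rpm_human.tsv").set_index("locus_id")
    rpm_m = read_table(DATA / "rpm_mouse.tsv").set_index("locus_id")
    peaks_h = read_bed(DATA / "peaks_human.bed", extra_cols=("locus_id",))
    peaks_m = read_bed(DATA / "peaks_mouse.bed", extra_cols=("locus_id",))

    # Recover per-species locus ids by peak coordinates (peaks are disjoint).
    rec = rec.merge(
        peaks_h.rename(columns={"start": "human_start", "locus_id": "locus_hid"})
        [["human_start", "locus_hid"]], on="human_start", how="left")
    rec = rec.merge(
        peaks_m.rename(columns={"start": "mouse_start", "locus_id": "locus_mid"})
        [["mouse_start", "locus_mid"]], on="mouse_start", how="left")
    rec.loc[~rec["human_peak"], "locus_hid"] = None
    rec.loc[~rec["mouse_peak"], "locus_mid"] = None
    rec["locus_id"] = rec["locus_hid"].where(rec["locus_hid"].notna(),
                                             rec["locus_mid"])
    rec["rpm_human"] = rpm_h["aTreg"].reindex(rec["locus_id"]).fillna(0).to_numpy()
    rec["rpm_mouse"] = rpm_m["aTreg"].reindex(rec["locus_id"]).fillna(0).to_numpy()

    active_both = rec["human_peak"] & rec["mouse_peak"]
    r, p = epigenetic_correlation(rec[active_both])
    write_table(pd.DataFrame([{"cell_type": "aTreg", "pearson_r": r, "p": p,
                               "n": int(active_both.sum())}]),
                RESULTS / "conservation_correlation.tsv")
    print(f"cross-species aTreg acetylation correlation (conserved, "
          f"active-both loci, n={int(active_both.sum())}): r = {r:.3f}")

    strata = rpm_quantile_strata(rec["rpm_human"], 5)
    frac = conserved_fraction_by_stratum(rec, strata)
    write_table(frac, RESULTS / "conserved_fractions.tsv")
    print("conserved fraction by human aTreg signal quintile (0 = weakest):")
    print(frac.to_string(index=False))


if __name__ == "__main__":
    main()
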