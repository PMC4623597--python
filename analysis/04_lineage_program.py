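"""Classify lineage-specific elements and test cross-species conservation.

Computes aTreg-vs-Teff fold changes per species over the atlas,
classifies each locus (up/down/ns per species), tests the overlap of the
per-species lineage-specific sets by one-sided hypergeometric
enrichment, sweeps rank cutoffs, relates element classes to nearby gene
expression (KS), and runs the mobility / functional-homology analysis.
Writes results/lineage_classes.tsv, results/lineage_enrichment.tsv,
results/rank_scan.tsv, results/expression_concordance.tsv and
results/mobility_report.tsv.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np
import pandas as pd

from common import DATA, RESULTS, SEED, ensure_dirs
from epicon.io import read_bed, read_table, write_table
from epicon.lineage import (
    assign_to_genes,
    classify_specificity,
    expression_concordance,
    lfc,
    mobility_analysis,
    overlap_enrichment_from_labels,
    rank_cutoff_scan,
)


def main() -> None:
    ensure_dirs()
    rec = read_table(RESULTS / "atlas.tsv")
    rpm_h = read_table(DATA / "rpm_human.tsv").set_index("locus_id")
    rpm_m = read_table(DATA / "rpm_mouse.tsv").set_index("locus_id")
    peaks_h = read_bed(DATA / "peaks_human.bed", extra_cols=("locus_id",))
    peaks_m = read_bed(DATA / "peaks_mouse.bed", extra_cols=("locus_id",))
    genes_h = read_table(DATA / "genes_human.tsv")
    genes_m = read_table(DATA / "genes_mouse.tsv")
    expr_h = read_table(DATA / "expression_human.tsv")
    expr_m = read_table(DATA / "expression_mouse.tsv")
    homology = read_table(DATA / "homology.tsv")

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

    def species_lfc(rpm, active):
        treg = rpm["aTreg"].reindex(rec["locus_id"]).to_numpy()
        teff = rpm["Teff"].reindex(rec["locus_id"]).to_numpy()
        vals = lfc(np.nan_to_num(treg), np.nan_to_num(teff))
        return np.where(active, vals, np.nan)

    active_h = (rec["genetic_status"] != "mouse-only").to_numpy()
    active_m = (rec["genetic_status"] != "human-only").to_numpy()
    rec["lfc_human"] = species_lfc(rpm_h, active_h)
    rec["lfc_mouse"] = species_lfc(rpm_m, active_m)

    classified = classify_specificity(rec, tau=1.0)
    write_table(
        classified[["atlas_id", "locus_id", "genetic_status", "lfc_human",
                    "lfc_mouse", "class_human", "class_mouse",
                    "class_combined"]],
        RESULTS / "lineage_classes.tsv")

    rows = [dict(direction=d, **overlap_enrichment_from_labels(classified, d))
            for d in ("up", "down")]
    enr = pd.DataFrame(rows)
    write_table(enr, RESULTS / "lineage_enrichment.tsv")
    print("cross-species overlap of lineage-specific sets "
          "(hypergeometric, conserved universe):")
    print(enr.to_string(index=False))

    conserved = classified[classified["genetic_status"] == "conserved"]
    scan = rank_cutoff_scan(
        conserved["lfc_human"].to_numpy(), conserved["lfc_mouse"].to_numpy(),
        ranks=[10, 25, 50, 100, 200], direction="up")
    write_table(scan, RESULTS / "rank_scan.tsv")

    # expression concordance per combined class, human expression axis
    el_h = classified[classified["human_peak"]].copy()
    el_h["chrom"] = el_h["human_chrom"]
    el_h["start"] = el_h["human_start"]
    el_h["end"] = el_h["human_end"]
    assign = assign_to_genes(el_h[["atlas_id", "chrom", "start", "end"]],
                             genes_h)
    nearest = {a.atlas_id: a.nearest for a in assign}
    el_h["gene_human"] = el_h["atlas_id"].map(nearest)
    expr_map = dict(zip(expr_h["gene"], expr_h["lfc"]))
    class_genes = {
        cls: sub["gene_human"].dropna().tolist()
        for cls, sub in el_h.groupby("class_combined")
        if cls in ("up-up", "down-down", "up-ns", "down-ns", "ns-up", "ns-down")
    }
    conc = expression_concordance(class_genes, expr_map)
    write_table(conc, RESULTS / "expression_concordance.tsv")
    print("\nexpression change of genes near element classes (KS vs all):")
    print(conc.to_string(index=False))

    # mobility / functional homology
    mouse2human = dict(zip(homology["mouse_gene"], homology["human_gene"]))
    el = el_h.copy()
    el["gene_mouse"] = el["gene_human"]  # ids already in human space
    el["rpm_human"] = rpm_h["aTreg"].reindex(el["locus_id"]).fillna(0).to_numpy()
    el["rpm_mouse"] = rpm_m["aTreg"].reindex(el["locus_id"]).fillna(0).to_numpy()
    expr_m_h = {
        mouse2human.get(g, g): v for g, v in zip(expr_m["gene"], expr_m["lfc"])
    }
    expr_q = dict(zip(expr_h["gene"], expr_h["q"]))
    report = mobility_analysis(el, expr_map, expr_m_h, expr_q,
                               n_perm=1000, seed=SEED)
    rep_df = pd.DataFrame([{k: v for k, v in report.items()
                            if not isinstance(v, list)}])
    write_table(rep_df, RESULTS / "mobility_report.tsv")
    print(f"\nmobility: {report['n_concordant']}/{report['n_mobile']} mobile "
          f"genes expression-concordant (perm p = {report['p_mobility']:.3g}); "
          f"{report['n_inactivated_human_ls']} human-LS / "
          f"{report['n_inactivated_mouse_ls']} mouse-LS elements inactive at "
          "the ortholog")


if __name__ == "__main__":
    main()
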