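"""Synthetic-data generators: chain validity, planted truth, reproducibility."""
import numpy as np
import pandas as pd
import pytest

from epicon.chains import ChainSet, map_interval, parse_chain_file, write_chain_file
from epicon.intervals import GenomicInterval as GI
from epicon.sim import (
    SimulationConfig,
    read_vcf,
    simulate_cohort,
    simulate_epigenome,
    simulate_genome_pair,
    simulate_gwas_catalog,
    simulate_reads,
    write_vcf,
)
from epicon.signal import quantify_rpm


class TestGenomePair:
    def test_zero_rates_give_identity_chain(self):
        cfg = SimulationConfig(seed=1, chrom_sizes={"chrA1": 10_000},
                               insertion_rate=0, deletion_rate=0,
                               inversion_rate=0, break_rate=0)
        pair = simulate_genome_pair(cfg)
        assert len(pair.chains) == 1
        res = map_interval(GI("chrA1", 2000, 2500), pair.chains)
        assert res.mapped.start == 2000 and res.mapped.end == 2500

    def test_deletion_unmaps_interior_and_offsets_flank(self):
        cfg = SimulationConfig(seed=2, chrom_sizes={"chrA1": 10_000},
                               insertion_rate=0, deletion_rate=0,
                               inversion_rate=0, break_rate=0)
        pair = simulate_genome_pair(cfg)
        # splice a 1 kb deletion by hand into the segment table semantics:
        # simulate with a high deletion rate until one event lands
        cfg2 = SimulationConfig(seed=5, chrom_sizes={"chrA1": 10_000},
                                insertion_rate=0, deletion_rate=2e-4,
                                inversion_rate=0, break_rate=0,
                                event_size_mean=1000)
        pair2 = simulate_genome_pair(cfg2)
        gaps = pair2.segments.sort_values("a_start")
        assert len(gaps) >= 2
        g0, g1 = gaps.iloc[0], gaps.iloc[1]
        del_lo, del_hi = int(g0["a_end"]), int(g1["a_start"])
        assert del_hi > del_lo
        inside = GI("chrA1", del_lo, del_hi)
        assert map_interval(inside, pair2.chains).status == "unmapped"
        flank = GI("chrA1", int(g1["a_start"]), int(g1["a_start"]) + 50)
        res = map_interval(flank, pair2.chains)
        assert res.status == "full"
        assert res.mapped.start == int(g1["b_start"])

    def test_inversion_emits_minus_strand_chain(self):
        cfg = SimulationConfig(seed=8, chrom_sizes={"chrA1": 50_000},
                               insertion_rate=0, deletion_rate=0,
                               inversion_rate=2e-4, break_rate=0,
                               event_size_mean=500)
        pair = simulate_genome_pair(cfg)
        minus = [c for c in pair.chains if c.q_strand == "-"]
        assert minus
        seg = pair.segments[pair.segments["strand"] == "-"].iloc[0]
        a0 = int(seg["a_start"])
        t0 = pair.map_base("chrA1", a0)
        t1 = pair.map_base("chrA1", a0 + 1)
        assert t1[1] == t0[1] - 1  # mapped order reverses

    def test_chains_satisfy_invariants_and_round_trip(self, tmp_path,
                                                      random_genome_pair):
        path = tmp_path / "pair.chain"
        write_chain_file(random_genome_pair.chains, path)
        assert parse_chain_file(path) == random_genome_pair.chains

    def test_degenerate_chrom_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, chrom_sizes={"chrA1": 0})


class TestEpigenome:
    def test_planted_lfc_recovered_in_expectation(self):
        props = {"conserved_active": 0.8, "both_ls": 0.1, "human_only_ls": 0.05,
                 "mouse_only_ls": 0.05}
        cfg = SimulationConfig(seed=9, n_loci=2000, class_proportions=props)
        sim = simulate_epigenome(cfg)
        truth = sim.truth.loci
        both = truth[truth["cls"] == "both_ls"]
        assert len(both) > 100
        from epicon.lineage import lfc
        treg = sim.signal_h.rpm.filter(like="aTreg").mean(axis=1)
        teff = sim.signal_h.rpm.filter(like="Teff").mean(axis=1)
        est = pd.Series(lfc(treg.to_numpy(), teff.to_numpy()),
                        index=sim.signal_h.rpm.index)
        planted = both.set_index("locus_id")["lfc_human"]
        err = (est.loc[planted.index] - planted).abs()
        assert err.median() < 0.5

    def test_conserved_active_lfc_near_zero(self):
        cfg = SimulationConfig(seed=10, n_loci=1000)
        sim = simulate_epigenome(cfg)
        truth = sim.truth.loci
        ca = truth[truth["cls"] == "conserved_active"]["locus_id"]
        from epicon.lineage import lfc
        treg = sim.signal_h.rpm.filter(like="aTreg").mean(axis=1)
        teff = sim.signal_h.rpm.filter(like="Teff").mean(axis=1)
        est = pd.Series(lfc(treg.to_numpy(), teff.to_numpy()),
                        index=sim.signal_h.rpm.index).loc[ca]
        assert abs(est.mean()) < 0.1

    def test_same_seed_identical_outputs(self):
        a = simulate_epigenome(SimulationConfig(seed=12, n_loci=150))
        b = simulate_epigenome(SimulationConfig(seed=12, n_loci=150))
        pd.testing.assert_frame_equal(a.signal_h.rpm, b.signal_h.rpm)
        pd.testing.assert_frame_equal(a.truth.loci, b.truth.loci)

    def test_read_level_realisation_matches_counts(self, rng):
        cfg = SimulationConfig(seed=14, n_loci=30)
        sim = simulate_epigenome(cfg)
        counts = sim.signal_h.rpm[["aTreg_1"]].round().astype(int)
        reads = simulate_reads(sim.peaks_h, counts, rng)
        reads["sample"] = "aTreg_1"
        m = quantify_rpm(sim.peaks_h, reads, totals={"aTreg_1": 10**6})
        got = m.rpm["aTreg_1"]
        want = counts["aTreg_1"].reindex(got.index).fillna(0)
        active = want.index[want > 0]
        assert (got.loc[active] == want.loc[active]).all()


class TestCohort:
    def test_het_depths_sum_to_total(self):
        cfg = SimulationConfig(seed=15)
        el = pd.DataFrame({"chrom": ["chrA1"], "start": [0], "end": [3000]})
        cohort = simulate_cohort(cfg, el)
        d = cohort.chip_depths
        assert (d["ref"] + d["alt"] >= 0).all()
        het = cohort.genotypes[cohort.genotypes["genotype"] == "het"]
        assert set(d["donor"]).issubset(set(het["donor"]))

    def test_ld_blocks_are_perfectly_linked_in_panel(self):
        cfg = SimulationConfig(seed=16, variants_per_element=4.0,
                               ld_block_size=2)
        el = pd.DataFrame({"chrom": ["chrA1"], "start": [0], "end": [3000]})
        cohort = simulate_cohort(cfg, el)
        from epicon.allelic import haplotype_r2
        mat = cohort.panel["eur"]
        v = cohort.variants
        found_linked = False
        for i in range(len(v) - 1):
            r2 = haplotype_r2(mat.iloc[i].to_numpy(), mat.iloc[i + 1].to_numpy())
            if r2 > 0.99:
                found_linked = True
        assert found_linked

    def test_vcf_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=17)
        el = pd.DataFrame({"chrom": ["chrA1"], "start": [0], "end": [3000]})
        cohort = simulate_cohort(cfg, el)
        path = tmp_path / "cohort.vcf"
        write_vcf(cohort, path)
        geno, depths = read_vcf(path)
        orig = cohort.genotypes.sort_values(["variant", "donor"]).reset_index(
            drop=True)
        got = geno.sort_values(["variant", "donor"]).reset_index(drop=True)
        assert (orig["genotype"].to_numpy() == got["genotype"].to_numpy()).all()

    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(seed=18)
        el = pd.DataFrame({"chrom": ["chrA1"], "start": [0], "end": [3000]})
        a = simulate_cohort(cfg, el)
        b = simulate_cohort(cfg, el)
        pd.testing.assert_frame_equal(a.chip_depths, b.chip_depths)


class TestCatalog:
    def setup_catalog(self, factor, seed=19, n=400):
        cfg = SimulationConfig(seed=seed, n_catalog_snps=n,
                               enrichment_factor={"autoimmune": factor,
                                                  "metabolic": 1.0,
                                                  "psychiatric": 1.0})
        regions = pd.DataFrame({"chrom": ["chrA1"], "start": [0],
                                "end": [500_000]})
        return simulate_gwas_catalog(cfg, regions, {"chrA1": 10_000_000})

    def test_study_size_straddles_filter(self):
        catalog, _ = self.setup_catalog(1.0)
        from epicon.disease import filter_studies
        sizes = catalog.groupby("study")["variant"].nunique()
        kept = filter_studies(catalog)
        assert (sizes <= 5).any()  # some studies fail the filter...
        assert kept["study"].nunique() < catalog["study"].nunique()

    def test_enrichment_factor_shifts_inside_fraction(self):
        cat1, truth1 = self.setup_catalog(1.0, seed=20)
        cat5, truth5 = self.setup_catalog(5.0, seed=21)
        f1 = truth1.catalog.groupby("disease_set")["planted_inside"].mean()
        f5 = truth5.catalog.groupby("disease_set")["planted_inside"].mean()
        assert f5["autoimmune"] > f1["autoimmune"] + 0.05
        assert abs(f5["psychiatric"] - f1["psychiatric"]) < 0.1
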