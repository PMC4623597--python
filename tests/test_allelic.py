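"""Allele-specific calling: dedup, filters, binomial tests, aggregation,
zygosity-normalised genotype association."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicon import allelic
from epicon.sim import SimulationConfig, simulate_cohort


class TestDedup:
    def reads(self):
        rows = [("chr1", 100, "+", i) for i in range(5)]
        rows += [("chr1", 200, "-", 9)]
        return pd.DataFrame(rows, columns=["chrom", "start", "strand", "idx"])

    def test_one_read_per_position_key(self):
        out = allelic.dedup_random(self.reads(), seed=3)
        assert len(out) == 2
        assert set(zip(out["chrom"], out["start"], out["strand"])) == {
            ("chr1", 100, "+"), ("chr1", 200, "-")
        }

    def test_unique_keys_pass_through(self):
        df = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [1, 2, 3],
                           "strand": ["+", "+", "-"]})
        out = allelic.dedup_random(df, seed=0)
        assert len(out) == 3

    def test_same_seed_same_selection(self):
        a = allelic.dedup_random(self.reads(), seed=11)
        b = allelic.dedup_random(self.reads(), seed=11)
        assert list(a["idx"]) == list(b["idx"])

    def test_selection_is_uniform(self):
        counts = np.zeros(5)
        for s in range(400):
            out = allelic.dedup_random(self.reads(), seed=s)
            kept = out[out["start"] == 100]["idx"].iloc[0]
            counts[kept] += 1
        # each duplicate should be chosen ~80 times of 400
        assert counts.min() > 40 and counts.max() < 140


class TestBinomial:
    @pytest.mark.parametrize("ref,alt,expected", [
        (5, 5, 1.0),
        (10, 0, 2 / 1024),
        (8, 2, 112 / 1024),
    ])
    def test_exact_values(self, ref, alt, expected):
        assert allelic.binom_two_tailed(ref, alt) == pytest.approx(expected)

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            allelic.binom_two_tailed(0, 0)

    def test_vectorized_matches_scalar(self, rng):
        n = rng.integers(1, 60, size=200)
        x = rng.binomial(n, 0.5)
        vec = allelic.binom_two_tailed_vec(x, n)
        for xi, ni, pi in zip(x, n, vec):
            assert pi == pytest.approx(
                allelic.binom_two_tailed(int(xi), int(ni - xi))
            )

    def test_type_one_error_conservative_but_not_degenerate(self, rng):
        x = rng.binomial(20, 0.5, size=10_000)
        p = allelic.binom_two_tailed_vec(x, np.full(10_000, 20))
        frac = (p < 0.05).mean()
        assert 0.02 <= frac <= 0.05


class TestPrefilter:
    def test_boundary_inclusive(self):
        s = pd.Series([0.21, 0.2, 0.05], index=list("abc"))
        out = allelic.prefilter_snps(s)
        assert list(out.index) == ["b", "c"]

    def test_empty_input_empty_output(self):
        assert len(allelic.prefilter_snps(pd.Series(dtype=float))) == 0


class TestHetSnpFilter:
    def calls(self, genotypes, pass_qc=True):
        return pd.DataFrame({
            "donor": [f"D{i}" for i in range(len(genotypes))],
            "variant": "rs1",
            "genotype": genotypes,
            "pass_qc": pass_qc,
        })

    def inputs(self, ref=10, alt=10):
        return pd.DataFrame({"variant": ["rs1"], "ref": [ref], "alt": [alt]})

    def test_het_in_one_donor_dropped(self):
        calls = self.calls(["het", "hom-ref", "hom-ref", "hom-alt"])
        assert len(allelic.filter_het_snps(calls, self.inputs())) == 0

    def test_imbalanced_input_dropped(self):
        calls = self.calls(["het", "het", "hom-ref", "hom-alt"])
        # (20, 5): two-tailed binomial p ~ 0.0041 < 0.05
        assert len(allelic.filter_het_snps(calls, self.inputs(20, 5))) == 0

    def test_good_variant_retained(self):
        calls = self.calls(["het", "het", "het", "hom-ref", "hom-alt"])
        out = allelic.filter_het_snps(calls, self.inputs())
        assert list(out["variant"]) == ["rs1"]
        assert out.loc[0, "n_het"] == 3

    def test_missing_input_record_warns_and_drops(self):
        calls = self.calls(["het", "het", "hom-ref", "hom-alt"])
        empty = pd.DataFrame({"variant": [], "ref": [], "alt": []})
        with pytest.warns(UserWarning, match="input"):
            out = allelic.filter_het_snps(calls, empty)
        assert len(out) == 0

    def test_failed_qc_drops(self):
        calls = self.calls(["het", "het", "hom-ref", "hom-alt"],
                           pass_qc=[True, False, True, True])
        assert len(allelic.filter_het_snps(calls, self.inputs())) == 0


class TestLdCollapse:
    def panel_from(self, hap_cols):
        """hap_cols: variants x haplotypes 0/1 matrix."""
        mat = pd.DataFrame(hap_cols, index=[f"rs{i}" for i in
                                            range(len(hap_cols))])
        return {p: mat for p in ("afr", "eur", "ceu", "chb", "jpt")}

    def variants(self, n, depths=None):
        return pd.DataFrame({
            "variant": [f"rs{i}" for i in range(n)],
            "element": "e1",
            "depth": depths or [10] * n,
        })

    def test_perfectly_linked_pair_collapses_to_highest_depth(self):
        panel = self.panel_from([[0, 1, 0, 1], [0, 1, 0, 1]])
        out = allelic.ld_collapse(self.variants(2, [10, 30]), panel)
        assert list(out["variant"]) == ["rs1"]
        assert out.loc[0, "n_collapsed"] == 2

    def test_independent_variants_both_kept(self):
        panel = self.panel_from([[0, 1, 0, 1], [0, 0, 1, 1]])
        out = allelic.ld_collapse(self.variants(2), panel)
        assert len(out) == 2

    def test_r2_matches_hand_computation_on_toy_haplotypes(self):
        # 4 haplotypes: D = 2/4 - (1/2)(1/2) = 0.25, r2 = 1
        h1 = np.array([1, 1, 0, 0])
        h2 = np.array([1, 1, 0, 0])
        assert allelic.haplotype_r2(h1, h2) == pytest.approx(1.0)
        # D = 1/4 - (1/2)(1/2) = 0; r2 = 0
        h3 = np.array([1, 0, 1, 0])
        assert allelic.haplotype_r2(h1, h3) == pytest.approx(0.0)
        # mixed case: p1=3/4, p2=1/2, p11=1/2, D=1/8
        h4 = np.array([1, 1, 1, 0])
        r2 = (1 / 8) ** 2 / ((3 / 4) * (1 / 4) * (1 / 2) * (1 / 2))
        assert allelic.haplotype_r2(h4, h3) == pytest.approx(r2)

    def test_variant_absent_from_panel_kept_with_warning(self):
        panel = self.panel_from([[0, 1, 0, 1]])  # only rs0
        with pytest.warns(UserWarning, match="absent"):
            out = allelic.ld_collapse(self.variants(2), panel)
        assert len(out) == 2


class TestAggregation:
    def test_fisher_statistic_value(self):
        res = allelic.aggregate_element([0.01, 0.04], n_null=10_000, seed=0)
        assert res.statistic == pytest.approx(-2 * (np.log(0.01) + np.log(0.04)))
        assert res.statistic == pytest.approx(15.648, abs=5e-3)

    def test_single_p_identity_aggregation(self):
        res = allelic.aggregate_element([0.05], n_null=200_000, seed=1)
        assert res.empirical_p == pytest.approx(0.05, abs=0.003)

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_chi2_limit(self, k):
        rng = np.random.default_rng(k)
        p = rng.uniform(size=k)
        res = allelic.aggregate_element(p, n_null=100_000, seed=7)
        assert res.empirical_p == pytest.approx(
            stats.chi2.sf(res.statistic, 2 * k), abs=0.01
        )

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = allelic.aggregate_element([0.0, 0.5], n_null=1000, seed=0)
        assert np.isfinite(res.statistic)

    def test_depth_matched_null_is_uniform_for_null_elements(self):
        rng = np.random.default_rng(5)
        pvals = []
        for i in range(400):
            dep = rng.poisson(25, size=3) + 1
            ref = rng.binomial(dep, 0.5)
            _, p = allelic.element_empirical_p(ref, dep, n_null=2000, seed=i)
            if not np.isnan(p):
                pvals.append(p)
        assert len(pvals) > 80
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestQq:
    def test_uniform_grid_on_diagonal(self):
        n = 99
        p = (np.arange(1, n + 1)) / (n + 1)
        qq = allelic.qq_summary(p)
        assert np.allclose(qq["observed"], qq["expected"], atol=1e-12)

    def test_cap_applied(self):
        qq = allelic.qq_summary([1e-9, 0.5])
        assert qq["observed"].max() == 5.0

    def test_planted_signal_diverges_above_diagonal(self, rng):
        null = rng.uniform(size=500)
        hits = rng.uniform(0, 1e-4, size=20)
        qq = allelic.qq_summary(np.concatenate([null, hits]))
        tail = qq.head(20)
        assert (tail["observed"] > tail["expected"]).all()


class TestZygosity:
    def table(self):
        return pd.DataFrame({
            "individual": ["a", "b", "c", "d"],
            "genotype": ["het", "hom-ref", "hom-ref", "hom-ref"],
            "value": [2.0, 4.0, 4.0, 4.0],
            "n_reads": [20, 20, 20, 5],
        })

    def test_het_doubled_then_mean_normalised(self):
        out = allelic.zygosity_normalize(self.table())
        # individual d excluded (5 reads is not "more than 5")
        assert len(out) == 3
        assert out["normalized"].mean() == pytest.approx(1.0)
        het = out[out["genotype"] == "het"]["normalized"].iloc[0]
        hom = out[out["genotype"] == "hom-ref"]["normalized"].iloc[0]
        assert het == pytest.approx(hom)  # 2*2.0 == 4.0 pre-normalisation

    def test_equal_homozygous_cohort_normalises_to_one(self):
        df = self.table().assign(genotype="hom-ref", value=7.0)
        out = allelic.zygosity_normalize(df)
        assert np.allclose(out["normalized"], 1.0)

    def test_all_excluded_is_an_error(self):
        df = self.table().assign(n_reads=2)
        with pytest.raises(ValueError):
            allelic.zygosity_normalize(df)

    def test_product_rule(self):
        assert allelic.combined_zygosity_test(0.01, 0.1)["p"] == pytest.approx(0.001)
        assert allelic.combined_zygosity_test(1.0, 1.0)["p"] == 1.0

    def test_missing_side_flagged(self):
        out = allelic.combined_zygosity_test(None, 0.2)
        assert out["p"] == 0.2 and not out["complete"]

    def test_concordant_effect_makes_product_smaller_than_parts(self, rng):
        wins = 0
        for i in range(100):
            r = np.random.default_rng(i)
            het_ref = r.binomial(40, 0.7)
            p_het = allelic.binom_two_tailed(het_ref, 40 - het_ref)
            hom_r = r.normal(1.3, 0.2, size=5)
            hom_a = r.normal(0.7, 0.2, size=5)
            p_hom = allelic.hom_group_ttest(hom_r, hom_a)
            p = allelic.combined_zygosity_test(p_het, p_hom)["p"]
            wins += p <= min(p_het, p_hom)
        assert wins == 100  # product never exceeds either factor


class TestGenotypeRegression:
    def test_perfect_linear_fit(self):
        res = allelic.genotype_regression([0, 1, 2, 3], [0, 1, 2, 3])
        assert res["slope"] == pytest.approx(1.0)
        assert res["stderr"] == pytest.approx(0.0, abs=1e-12)

    def test_codes_expansion_for_heterozygotes(self):
        df = pd.DataFrame({
            "genotype": ["hom-ref", "het", "hom-alt"],
            "value": [0.5, np.nan, 3.5],
            "value_ref": [np.nan, 1.4, np.nan],
            "value_alt": [np.nan, 2.2, np.nan],
        })
        out = allelic.genotype_codes(df)
        assert list(out["code"]) == [0.0, 1.0, 2.0, 3.0]
        assert list(out["value"]) == [0.5, 1.4, 2.2, 3.5]

    def test_planted_slope_recovery(self):
        hits = 0
        for i in range(60):
            r = np.random.default_rng(100 + i)
            x = np.repeat([0.0, 1.0, 2.0, 3.0], 5)
            y = 0.5 * x + r.normal(0, 0.1, size=len(x))
            res = allelic.genotype_regression(y, x)
            hits += 0.4 <= res["slope"] <= 0.6
        assert hits >= 57  # >= 95% of simulations

    def test_identical_groups_null_slope_difference(self):
        x = [0.0, 1.0, 2.0, 3.0] * 3
        y = [v * 0.7 + 0.1 for v in x]
        res = allelic.slope_comparison(x, y, x, y)
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert res["df"] == len(x) * 2 - 4

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            allelic.genotype_regression([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestPipeline:
    def test_null_pipeline_calibration_small(self):
        cfg = SimulationConfig(seed=31, ase_fraction=0.0)
        elements = pd.DataFrame({"chrom": "chrA1",
                                 "start": np.arange(200) * 5000,
                                 "end": np.arange(200) * 5000 + 3000})
        cohort = simulate_cohort(cfg, elements)
        res = allelic.ase_pipeline(cohort.genotypes, cohort.chip_depths,
                                   cohort.input_depths, cohort.panel,
                                   n_null=3000, seed=1)
        p = res["empirical_p"].dropna()
        assert len(p) > 20
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_ase_detected(self):
        cfg = SimulationConfig(seed=32, ase_fraction=1.0, ase_theta=0.75)
        elements = pd.DataFrame({"chrom": "chrA1",
                                 "start": np.arange(80) * 5000,
                                 "end": np.arange(80) * 5000 + 3000})
        cohort = simulate_cohort(cfg, elements)
        res = allelic.ase_pipeline(cohort.genotypes, cohort.chip_depths,
                                   cohort.input_depths, cohort.panel,
                                   n_null=3000, seed=1)
        tested = res.dropna(subset=["empirical_p"])
        assert (tested["empirical_p"] < 0.05).mean() >= 0.8
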