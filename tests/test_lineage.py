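"""Lineage-specificity classes, overlap enrichment, gene linkage, mobility."""
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicon.lineage import (
    assign_to_genes,
    classify_specificity,
    expression_concordance,
    lfc,
    mobility_analysis,
    overlap_enrichment,
    overlap_enrichment_from_labels,
    rank_cutoff_scan,
)


class TestLfc:
    def test_known_value(self):
        assert lfc(7.5, 1.5) == pytest.approx(2.0)

    def test_zero_zero_is_symmetric(self):
        assert lfc(0.0, 0.0) == 0.0

    @pytest.mark.parametrize("x", [0.0, 0.5, 3.7, 100.0])
    def test_equal_inputs_give_zero(self, x):
        assert lfc(x, x) == 0.0

    def test_negative_rpm_rejected(self):
        with pytest.raises(ValueError):
            lfc(-1.0, 2.0)


class TestClassify:
    def frame(self, h, m, status="conserved"):
        return pd.DataFrame({"lfc_human": h, "lfc_mouse": m,
                             "genetic_status": status})

    def test_threshold_application(self):
        out = classify_specificity(self.frame([1.5, 1.5, 1.5],
                                              [1.2, 0.1, -1.5]), tau=1.0)
        assert list(out["class_combined"]) == ["up-up", "up-ns", "up-down"]

    def test_species_only_locus_classified_in_its_species(self):
        out = classify_specificity(self.frame([1.5], [np.nan], "human-only"))
        assert out.loc[0, "class_human"] == "up"
        assert out.loc[0, "class_combined"] == "up-."

    def test_classes_partition_all_loci(self, rng):
        h = rng.normal(0, 1.5, size=500)
        m = rng.normal(0, 1.5, size=500)
        out = classify_specificity(self.frame(h, m))
        assert out["class_combined"].value_counts().sum() == 500
        combos = {f"{a}-{b}" for a in ("up", "down", "ns")
                  for b in ("up", "down", "ns")}
        assert set(out["class_combined"]) <= combos


class TestOverlapEnrichment:
    def test_exact_value_small_universe(self):
        # overlap 4 of human-5 x mouse-4 in N=10: C(5,4)C(5,0)/C(10,4)
        assert overlap_enrichment(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_zero_overlap_upper_tail_is_one(self):
        assert overlap_enrichment(10, 5, 4, 0) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        for N in (6, 10, 15):
            for K in (2, N // 2):
                for n in (3, N // 2):
                    for k in range(min(K, n) + 1):
                        hits = sum(
                            1 for draw in combinations(range(N), n)
                            if len(set(draw) & set(range(K))) >= k
                        )
                        exact = hits / comb(N, n)
                        assert overlap_enrichment(N, K, n, k) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError):
            overlap_enrichment(0, 0, 0, 0)

    def test_label_wrapper_counts_conserved_universe(self):
        df = pd.DataFrame({
            "genetic_status": ["conserved"] * 4 + ["human-only"],
            "class_human": ["up", "up", "ns", "ns", "up"],
            "class_mouse": ["up", "ns", "up", "ns", None],
        })
        res = overlap_enrichment_from_labels(df, "up")
        assert res["n_universe"] == 4
        assert res["n_overlap"] == 1


class TestRankScan:
    def test_identical_rankings_maximal_overlap(self, rng):
        v = rng.normal(size=50)
        out = rank_cutoff_scan(v, v, ranks=[5, 10, 20])
        assert list(out["overlap"]) == [5, 10, 20]
        assert (out["p"] < 0.01).all()

    def test_full_rank_forces_p_one(self, rng):
        h, m = rng.normal(size=30), rng.normal(size=30)
        out = rank_cutoff_scan(h, m, ranks=[30])
        assert out.loc[0, "overlap"] == 30
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_independent_rankings_give_unremarkable_p(self, rng):
        ps = []
        for _ in range(200):
            h, m = rng.normal(size=40), rng.normal(size=40)
            out = rank_cutoff_scan(h, m, ranks=[10])
            ps.append(out.loc[0, "p"])
        # null p-values should not pile up near zero
        assert np.mean(np.asarray(ps) < 0.05) < 0.12


class TestGeneAssignment:
    def genes(self):
        return pd.DataFrame({
            "gene": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "tss": [50_000, 400_000],
            "body_start": [50_000, 400_000],
            "body_end": [60_000, 410_000],
        })

    def test_window_rule(self):
        el = pd.DataFrame({"atlas_id": ["e1"], "chrom": ["chr1"],
                           "start": [100_000], "end": [101_000]})
        (a,) = assign_to_genes(el, self.genes())
        assert a.genes == ["A"]

    def test_nearest_gene_fallback(self):
        el = pd.DataFrame({"atlas_id": ["e1"], "chrom": ["chr1"],
                           "start": [650_000], "end": [651_000]})
        (a,) = assign_to_genes(el, self.genes())
        assert a.genes == ["B"]  # 240 kb away but nearest

    def test_element_inside_gene_body_included(self):
        el = pd.DataFrame({"atlas_id": ["e1"], "chrom": ["chr1"],
                           "start": [55_000], "end": [55_500]})
        (a,) = assign_to_genes(el, self.genes())
        assert "A" in a.genes

    def test_empty_gene_models_rejected(self):
        el = pd.DataFrame({"atlas_id": ["e1"], "chrom": ["chr1"],
                           "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            assign_to_genes(el, self.genes().iloc[:0])


class TestExpressionConcordance:
    def test_identical_samples_null_ks(self, rng):
        genes = [f"g{i}" for i in range(50)]
        expr = dict(zip(genes, rng.normal(size=50)))
        out = expression_concordance({"cls": genes}, expr, background_genes=genes)
        assert out.loc[0, "ks_d"] == pytest.approx(0.0)
        assert out.loc[0, "ks_p"] == pytest.approx(1.0)

    def test_planted_shift_detected(self, rng):
        bg = {f"g{i}": rng.normal() for i in range(500)}
        up = {f"u{i}": rng.normal(2.0, 1.0) for i in range(40)}
        expr = {**bg, **up}
        out = expression_concordance({"up_both": list(up)}, expr,
                                     background_genes=list(bg))
        assert out.loc[0, "ks_p"] < 0.01

    def test_small_class_reports_curve_but_skips_test(self):
        expr = {"a": 1.0, "b": 2.0, "c": 3.0}
        with pytest.warns(UserWarning, match="skipped"):
            out = expression_concordance({"tiny": ["a"]}, expr)
        assert np.isnan(out.loc[0, "ks_p"])


class TestMobility:
    def elements(self):
        # gene G1 has a human-LS element and a mouse-LS element at
        # different atlas loci (mobile); G2's element is LS in both at the
        # same locus (not mobile)
        return pd.DataFrame({
            "atlas_id": ["a1", "a2", "a3"],
            "genetic_status": ["conserved"] * 3,
            "class_human": ["up", "ns", "up"],
            "class_mouse": ["ns", "up", "up"],
            "gene_human": ["G1", "G1", "G2"],
            "gene_mouse": ["G1", "G1", "G2"],
            "lfc_human": [2.0, 0.1, 2.0],
            "lfc_mouse": [0.2, 2.0, 2.0],
            "rpm_human": [10.0, 10.0, 10.0],
            "rpm_mouse": [10.0, 10.0, 10.0],
        })

    def test_mobile_gene_detected_and_concordance_counted(self):
        expr_h = {"G1": 1.0, "G2": 1.0}
        expr_m = {"G1": 0.5, "G2": 1.0}
        rep = mobility_analysis(self.elements(), expr_h, expr_m, n_perm=200,
                                seed=1)
        assert rep["mobile_genes"] == ["G1"]
        assert rep["n_concordant"] == 1

    def test_no_lineage_specific_elements_all_zero(self):
        el = self.elements()
        el["class_human"] = "ns"
        el["class_mouse"] = "ns"
        rep = mobility_analysis(el, {}, {}, n_perm=100, seed=0)
        assert rep["n_mobile"] == 0
        assert rep["n_inactivated_human_ls"] == 0

    def test_deterministic_given_seed(self):
        expr_h = {"G1": 1.0, "G2": -1.0}
        expr_m = {"G1": 1.0, "G2": -0.5}
        a = mobility_analysis(self.elements(), expr_h, expr_m, n_perm=300, seed=9)
        b = mobility_analysis(self.elements(), expr_h, expr_m, n_perm=300, seed=9)
        assert a["p_mobility"] == b["p_mobility"]

    def test_inactive_ortholog_counted(self):
        el = self.elements()
        el.loc[0, "rpm_mouse"] = 0.2  # human-LS element inactive in mouse
        rep = mobility_analysis(el, {}, {}, n_perm=100, seed=0)
        assert rep["n_inactivated_human_ls"] == 1
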