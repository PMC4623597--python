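"""Disease-risk SNP enrichment and conservation partitioning."""
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicon.disease import (
    DiseaseSet,
    conservation_partition,
    enrichment_test,
    expand_risk_regions,
    filter_studies,
)


def catalog_frame(rows):
    return pd.DataFrame(rows, columns=["variant", "chrom", "pos", "trait",
                                       "study"])


class TestStudyFilter:
    def make(self, n_snps, study="s1"):
        return [(f"{study}_rs{i}", "chr1", 100 + i, "t1", study)
                for i in range(n_snps)]

    def test_five_snp_study_excluded(self):
        cat = catalog_frame(self.make(5))
        assert len(filter_studies(cat)) == 0

    def test_six_snp_study_included(self):
        cat = catalog_frame(self.make(6))
        assert len(filter_studies(cat)) == 6

    def test_empty_catalog(self):
        assert len(filter_studies(catalog_frame([]))) == 0


class TestRiskRegions:
    def test_plus_minus_100kb(self):
        el = pd.DataFrame({"chrom": ["chr1"], "start": [150_000],
                           "end": [150_500]})
        out = expand_risk_regions(el)
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (50_000, 250_500)

    def test_clipped_at_contig_start(self):
        el = pd.DataFrame({"chrom": ["chr1"], "start": [50_000],
                           "end": [50_500]})
        out = expand_risk_regions(el)
        assert out.loc[0, "start"] == 0

    def test_overlapping_regions_merge(self):
        el = pd.DataFrame({"chrom": ["chr1", "chr1"],
                           "start": [200_000, 320_000],
                           "end": [200_500, 320_500]})
        out = expand_risk_regions(el)
        assert len(out) == 1

    def test_gene_body_extension_beyond_window(self):
        el = pd.DataFrame({"chrom": ["chr1"], "start": [500_000],
                           "end": [500_500]})
        genes = pd.DataFrame({"gene": ["G"], "chrom": ["chr1"],
                              "tss": [480_000], "body_start": [480_000],
                              "body_end": [700_000]})
        out = expand_risk_regions(el, genes)
        assert out.loc[0, "end"] == 700_000

    def test_merged_regions_disjoint(self, rng):
        el = pd.DataFrame({"chrom": "chr1",
                           "start": rng.integers(0, 5_000_000, size=40)})
        el["end"] = el["start"] + 500
        out = expand_risk_regions(el)
        assert (out["start"].iloc[1:].to_numpy()
                >= out["end"].iloc[:-1].to_numpy()).all()


class TestEnrichment:
    def test_exact_small_universe(self):
        # N=10 variants, K=5 inside, disease set n=4 with k=4 inside
        rows = []
        for i in range(10):
            inside = i < 5
            trait = "t1" if (i < 4) else "bg"
            rows.append((f"rs{i}", "chr1", 100 if inside else 900_000,
                         trait, "s1"))
        cat = catalog_frame(rows)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        res = enrichment_test(DiseaseSet("ai", ("t1",)), cat, regions)
        assert res["k"] == 4
        assert res["p"] == pytest.approx(5 / 210)

    def test_matches_enumeration_for_small_universes(self):
        for N, K, n, k in [(8, 3, 4, 2), (12, 6, 5, 3), (20, 8, 6, 0)]:
            rows = []
            for i in range(N):
                inside = i < K
                # choose the disease variants to realise overlap k exactly
                trait = "t1" if (i < k or (K <= i < K + (n - k))) else "bg"
                rows.append((f"rs{i}", "chr1", 100 + i if inside else 10**6 + i,
                             trait, "s1"))
            cat = catalog_frame(rows)
            regions = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                    "end": [10_000]})
            res = enrichment_test(DiseaseSet("ai", ("t1",)), cat, regions)
            hits = sum(1 for draw in combinations(range(N), n)
                       if len([d for d in draw if d < K]) >= k)
            assert res["p"] == pytest.approx(hits / comb(N, n), abs=1e-12)

    def test_empty_disease_set_is_an_error(self):
        cat = catalog_frame([("rs0", "chr1", 5, "bg", "s1")])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            enrichment_test(DiseaseSet("ai", ("t1",)), cat, regions)

    def test_zero_overlap_p_near_one(self):
        rows = [(f"rs{i}", "chr1", 10**6 + i, "t1", "s1") for i in range(4)]
        rows += [(f"bg{i}", "chr1", 100 + i, "bg", "s2") for i in range(6)]
        cat = catalog_frame(rows)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        res = enrichment_test(DiseaseSet("ai", ("t1",)), cat, regions)
        assert res["k"] == 0
        assert res["p"] == pytest.approx(1.0)


class TestPartition:
    def frame(self):
        return pd.DataFrame({
            "disease_set": ["ai", "ai", "ai", "psych"],
            "genetic_status": ["conserved", "conserved", "human-only",
                               "conserved"],
            "class_human": ["up", "ns", "up", "ns"],
            "class_mouse": ["up", "ns", None, "ns"],
        })

    def test_deepest_category_wins(self):
        out = conservation_partition(self.frame())
        ai = out[out["disease_set"] == "ai"].set_index("category")["count"]
        assert ai["lineage_specific_both"] == 1
        assert ai["conserved"] == 1
        assert ai["non_conserved"] == 1

    def test_fractions_sum_to_one_per_set(self):
        out = conservation_partition(self.frame())
        sums = out.groupby("disease_set")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_unannotated_element_warned_as_unknown(self):
        df = self.frame()
        df.loc[0, "genetic_status"] = None
        with pytest.warns(UserWarning, match="lack conservation"):
            out = conservation_partition(df)
        assert "unknown" in set(out["category"])

    def test_planted_contrast_recovered(self, rng):
        # autoimmune risk elements planted in the deepest category,
        # psychiatric in non-conserved elements
        rows = []
        for i in range(60):
            rows.append(dict(disease_set="autoimmune",
                             genetic_status="conserved",
                             class_human="up", class_mouse="up"))
        for i in range(60):
            rows.append(dict(disease_set="psychiatric",
                             genetic_status="human-only",
                             class_human="up", class_mouse=None))
        out = conservation_partition(pd.DataFrame(rows))
        ai = out[(out["disease_set"] == "autoimmune")
                 & (out["category"] == "lineage_specific_both")]
        ps = out[(out["disease_set"] == "psychiatric")
                 & (out["category"] == "non_conserved")]
        assert ai["fraction"].iloc[0] == 1.0
        assert ps["fraction"].iloc[0] == 1.0
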