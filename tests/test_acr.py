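import numpy as np
import pandas as pd
import pytest

from subfrac import acr
from subfrac.partition import partition_from_boundaries

GENES = pd.DataFrame(
    {
        "gene_id": ["g1", "g2"],
        "chrom": ["c1", "c1"],
        "start": [10_000, 50_000],
        "end": [14_000, 54_000],
    }
)


def acr_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "acr_id", "score"])


class TestClassifyAcrs:
    def test_distance_classes(self):
        acrs = acr_frame(
            [
                ("c1", 12_000, 12_200, "a_genic", 1.0),  # inside g1
                ("c1", 8_300, 8_500, "a_prox", 1.0),  # 1,500 bp away
                ("c1", 7_300, 7_500, "a_dist", 1.0),  # 2,500 bp away
                ("c1", 7_800, 8_000, "a_edge", 1.0),  # exactly 2,000 bp
            ]
        )
        out = acr.classify_acrs(acrs, GENES)
        assert list(out["distance_class"]) == ["genic", "proximal", "distal", "proximal"]
        assert list(out["distance"]) == [0.0, 1_500.0, 2_500.0, 2_000.0]
        assert (out["nearest_gene"] == "g1").all()

    def test_nearest_gene_by_edge_distance(self):
        out = acr.classify_acrs(acr_frame([("c1", 30_000, 30_100, "a", 1.0)]), GENES)
        assert out["nearest_gene"].iloc[0] == "g1"  # 16,000 vs 19,900

    def test_geneless_chromosome_warns_distal(self):
        with pytest.warns(UserWarning, match="no genes"):
            out = acr.classify_acrs(acr_frame([("cX", 0, 100, "a", 1.0)]), GENES)
        assert out["distance_class"].iloc[0] == "distal"
        assert out["nearest_gene"].iloc[0] is None

    def test_classes_partition_all_acrs(self):
        rng = np.random.default_rng(2)
        rows = [
            ("c1", int(s), int(s) + 150, f"a{i}", 1.0)
            for i, s in enumerate(rng.integers(0, 60_000, 50))
        ]
        out = acr.classify_acrs(acr_frame(rows), GENES)
        assert out["distance_class"].isin(["genic", "proximal", "distal"]).all()


def status_series():
    return pd.Series(
        {"g_pair1": "pair", "g_pair2": "pair", "g_s1": "singleton_m1", "g_s2": "singleton_m2"}
    )


class TestRetentionRatio:
    @pytest.mark.parametrize(
        "n_singleton,n_wgd,expected", [(8523, 6484, 1.3), (2956, 5513, 0.5)]
    )
    def test_reported_ratio_convention(self, n_singleton, n_wgd, expected):
        assert round(n_singleton / n_wgd, 1) == expected

    def test_counts_and_exclusions(self):
        acrs = pd.DataFrame(
            {
                "acr_id": ["a1", "a2", "a3", "a4"],
                "nearest_gene": ["g_pair1", "g_s1", "g_unknown", None],
            }
        )
        status = status_series()
        sub = pd.Series(
            {"g_pair1": "maize1", "g_pair2": "maize1", "g_s1": "maize1", "g_s2": "maize2"}
        )
        ns, nw, ratio = acr.acr_retention_ratio(acrs, status, sub, "maize1")
        assert (ns, nw) == (1, 1)  # unknown/None nearest genes excluded
        assert ratio == 1.0

    def test_all_near_wgd_gives_zero(self):
        acrs = pd.DataFrame({"acr_id": ["a1"], "nearest_gene": ["g_pair1"]})
        sub = pd.Series({"g_pair1": "maize1"})
        ns, nw, ratio = acr.acr_retention_ratio(acrs, status_series(), sub, "maize1")
        assert (ns, nw, ratio) == (0, 1, 0.0)


class TestRetentionCategories:
    def _inputs(self):
        acrs = pd.DataFrame(
            {
                "acr_id": ["a1", "a2", "a3", "a4", "a5", "a6"],
                "nearest_gene": ["g_pair1", "g_pair1", "g_pair2", "g_s1", "g_s2", "g_pair1"],
            }
        )
        homology = pd.DataFrame(
            {
                "maize_acr": ["a1", "a2", "a3", "a4", "a5"],
                "subgenome": ["maize1", "maize2", "maize2", "maize1", "maize2"],
                "partner_acr": ["a2", "a1", None, None, None],
                "sorghum_acr": ["s1", "s1", "s2", "s3", "s4"],
            }
        )
        return acrs, homology

    def test_five_way_assignment(self):
        acrs, homology = self._inputs()
        with pytest.warns(UserWarning, match="absent"):
            cats = acr.assign_retention_category(acrs, homology, status_series())
        assert list(cats[:5]) == [1, 1, 3, 4, 5]
        assert pd.isna(cats.iloc[5])  # a6 not in the homology table

    def test_totals_bookkeeping_identity(self):
        """2*n(cat1 pairs) + n(cat2) + n(cat3) equals the near-WGD syntenic
        ACR count (category-1 ACRs are counted once per surviving copy)."""
        acrs, homology = self._inputs()
        with pytest.warns(UserWarning):
            cats = acr.assign_retention_category(acrs, homology, status_series())
        counts = acr.category_counts(cats)
        near_wgd_syntenic = 3  # a1, a2, a3
        assert counts[1] + counts[2] + counts[3] == near_wgd_syntenic
        assert counts[1] % 2 == 0  # paired ACRs come two at a time

    def test_biased_retention_on_synthetic_data(self, toy_pipeline):
        _, summary = toy_pipeline
        cats = summary["acr"]["retention_categories"]
        # generator retains maize1 ACRs more often than maize2 ACRs
        assert cats[2] > cats[3]
        assert cats[4] > cats[5]


class TestAccessibilityCompare:
    def test_identical_distributions_flat(self):
        rng = np.random.default_rng(1)
        scores = rng.lognormal(0, 0.3, 100)
        df = pd.DataFrame(
            {"group": ["a"] * 100 + ["b"] * 100, "score": np.concatenate([scores, scores])}
        )
        out = acr.accessibility_compare(df)
        tests = out.attrs["tests"]
        assert tests["difference"].iloc[0] == 0.0
        assert tests["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "group": ["m1_arm"] * 80 + ["m2_arm"] * 80,
                "score": np.concatenate(
                    [rng.normal(2.0, 0.5, 80), rng.normal(1.5, 0.5, 80)]
                ),
            }
        )
        out = acr.accessibility_compare(df)
        tests = out.attrs["tests"]
        assert tests["difference"].iloc[0] > 0
        assert tests["pvalue"].iloc[0] < 1e-4

    def test_tiny_group_is_na(self):
        df = pd.DataFrame({"group": ["a", "b", "b", "b"], "score": [1.0, 2.0, 3.0, 4.0]})
        out = acr.accessibility_compare(df).set_index("group")
        assert np.isnan(out.loc["a", "mean"])


class TestLoopCounts:
    parts = {
        "m1_c1": partition_from_boundaries("m1_c1", 10_000_000, (3_000_000, 7_000_000)),
        "m2_c1": partition_from_boundaries("m2_c1", 10_000_000, (3_000_000, 7_000_000)),
    }
    submap = {"m1_c1": "maize1", "m2_c1": "maize2"}

    def _loops(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        )

    def test_same_region_loop_counted(self):
        loops = self._loops([("m1_c1", 100, 200, "m1_c1", 50_000, 50_100)])
        out = acr.loop_region_counts(loops, self.parts, self.submap)
        out = out.set_index(["subgenome", "region"])["n_loops"]
        assert out[("maize1", "arm")] == 1
        assert out[("maize2", "arm")] == 0

    def test_arm_peri_loop_is_mixed(self):
        loops = self._loops([("m1_c1", 100, 200, "m1_c1", 5_000_000, 5_000_100)])
        out = acr.loop_region_counts(loops, self.parts, self.submap)
        assert out.set_index("subgenome").loc["mixed", "n_loops"] == 1

    def test_zero_loops_all_zero(self):
        out = acr.loop_region_counts(self._loops([]), self.parts, self.submap)
        assert (out["n_loops"] == 0).all()

    def test_off_chromosome_anchor_skipped(self):
        loops = self._loops([("chrX", 0, 10, "m1_c1", 0, 10)])
        with pytest.warns(UserWarning, match="skipped"):
            out = acr.loop_region_counts(loops, self.parts, self.submap)
        assert (out["n_loops"] == 0).all()
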