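import numpy as np
import pandas as pd
import pytest

from subfrac import fractionation as frac
from subfrac.partition import RecombinationMap


def raw_row(m1="g1", m2="g2", tandem=False, ks1=0.5, om1=0.3, ks2=0.5, om2=0.3):
    return {
        "maize1_gene": m1,
        "maize2_gene": m2,
        "sorghum_gene": "sb",
        "tandem": tandem,
        "ks_m1": ks1,
        "omega_m1": om1,
        "ks_m2": ks2,
        "omega_m2": om2,
    }


class TestFilterSyntelogs:
    def test_threshold_violations_are_removed_with_reasons(self):
        raw = pd.DataFrame(
            [
                raw_row(m1="a1", m2="a2"),
                raw_row(m1="b1", m2="b2", ks1=0.04),  # too recent
                raw_row(m1="c1", m2="c2", om2=2.5),  # implausible omega
                raw_row(m1="d1", m2="d2"),
                raw_row(m1="e1", m2="e2"),
            ]
        )
        kept, log = frac.filter_syntelogs(raw)
        assert len(kept) == 3 and len(log) == 2
        assert set(log["reason"]) == {"ks_min", "omega_max"}

    def test_tandem_and_incomplete_rows(self):
        raw = pd.DataFrame(
            [
                raw_row(m1="a1", m2="a2", tandem=True),
                raw_row(m1="b1", m2="b2", ks2=np.nan),
                raw_row(m1="c1", m2=None, ks2=np.nan, om2=np.nan),  # singleton: fine
            ]
        )
        kept, log = frac.filter_syntelogs(raw)
        assert list(log["reason"]) == ["tandem", "incomplete"]
        assert list(kept["status"]) == ["singleton_m1"]

    def test_boundary_values_survive(self):
        raw = pd.DataFrame([raw_row(ks1=0.05, om1=2.0)])
        kept, log = frac.filter_syntelogs(raw)
        assert len(kept) == 1 and len(log) == 0


class TestCategories:
    def test_four_way_mapping(self):
        assert frac.assign_category("arm", "arm") == "M1arm_M2arm"
        assert frac.assign_category("arm", "peri") == "M1arm_M2peri"
        assert frac.assign_category("peri", "arm") == "M1peri_M2arm"
        assert frac.assign_category("peri", "peri") == "M1peri_M2peri"
        with pytest.raises(ValueError):
            frac.assign_category("arm", "telomere")

    def test_category_counts_partition_pairs(self, toy_pipeline):
        out_dir, _ = toy_pipeline
        table = pd.read_csv(out_dir / "syntelogs_annotated.tsv", sep="\t")
        pairs = table[table["status"] == "pair"]
        assert pairs["category"].notna().all()
        assert pairs["category"].value_counts().sum() == len(pairs)


class TestSingletonWgdRatio:
    def _table(self, n_singleton, n_wgd, region="arm"):
        rows = []
        for i in range(n_singleton):
            rows.append(
                {"maize1_gene": f"s{i}", "maize2_gene": None, "status": "singleton_m1",
                 "region_m1": region, "region_m2": None}
            )
        for i in range(n_wgd):
            rows.append(
                {"maize1_gene": f"p{i}", "maize2_gene": f"q{i}", "status": "pair",
                 "region_m1": region, "region_m2": region}
            )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "n_singleton,n_wgd,expected",
        [(5937, 3597, 1.7), (2448, 3429, 0.7), (0, 100, 0.0)],
    )
    def test_reported_ratios(self, n_singleton, n_wgd, expected):
        # first case checked for maize1, second mirrors the maize2 bookkeeping
        table = self._table(n_singleton, n_wgd)
        ns, nw, ratio = frac.singleton_wgd_ratio(table, "maize1", "arm")
        assert (ns, nw) == (n_singleton, n_wgd)
        assert ratio == expected

    def test_zero_wgd_is_na(self):
        ns, nw, ratio = frac.singleton_wgd_ratio(self._table(3, 0), "maize1", "arm")
        assert np.isnan(ratio)


class TestRetentionRate:
    def test_formula_plug_in(self):
        assert frac.retention_rate(2, 1, 3) == pytest.approx(5 / 6)

    def test_no_partner_loss_gives_one(self):
        assert frac.retention_rate(0, 0, 7) == 1.0

    def test_aggregate_arm_counts(self):
        # aggregate (not per-block) application of the formula to the
        # arm-arm singleton/WGD totals 4,232 / 1,866 / 2,877
        assert frac.retention_rate(4232, 1866, 2877) == pytest.approx(7109 / 8975)

    def test_zero_denominator_is_na(self):
        assert np.isnan(frac.retention_rate(0, 0, 0))


def synth_table(runs):
    """Build an annotated table from (m1_chrom, m2_chrom, n_pairs) runs."""
    rows = []
    pos = {}
    for m1c, m2c, n in runs:
        for _ in range(n):
            p1 = pos.get(m1c, 0)
            p2 = pos.get(m2c, 0)
            rows.append(
                {
                    "maize1_gene": f"m1_{len(rows)}",
                    "maize2_gene": f"m2_{len(rows)}",
                    "status": "pair",
                    "m1_chrom": m1c,
                    "m2_chrom": m2c,
                    "m1_start": p1,
                    "m1_end": p1 + 3000,
                    "m2_start": p2,
                    "m2_end": p2 + 3000,
                    "region_m1": "arm",
                    "region_m2": "arm",
                }
            )
            pos[m1c] = p1 + 10_000
            pos[m2c] = p2 + 10_000
    return pd.DataFrame(rows)


class TestBuildBlocks:
    def test_single_run_is_one_block(self):
        table, blocks = frac.build_blocks(synth_table([("c1", "d1", 8)]))
        assert len(blocks) == 1
        assert blocks["n_pairs"].iloc[0] == 8

    def test_short_run_is_excluded(self):
        _, blocks = frac.build_blocks(synth_table([("c1", "d1", 4)]))
        assert len(blocks) == 0

    def test_twelve_planted_blocks_recovered(self):
        runs = [("c1", "d1" if i % 2 == 0 else "d2", 6) for i in range(12)]
        table, blocks = frac.build_blocks(synth_table(runs))
        assert len(blocks) == 12
        assert table["block_id"].notna().all()

    def test_singletons_extend_compatible_runs(self):
        t = synth_table([("c1", "d1", 6)])
        t.loc[2, ["maize2_gene", "m2_chrom", "m2_start", "m2_end", "region_m2"]] = [
            None, None, np.nan, np.nan, None,
        ]
        t.loc[2, "status"] = "singleton_m1"
        _, blocks = frac.build_blocks(t)
        assert len(blocks) == 1
        b = blocks.iloc[0]
        assert b["n_pairs"] == 5 and b["n_singleton_m1"] == 1
        assert b["retention_m1"] == 1.0
        assert b["retention_m2"] == pytest.approx(5 / 6)


class TestBlockStats:
    def test_density_te_and_recombination(self):
        # 30 pairs spanning exactly 2 Mb on each side
        rows = []
        for i in range(30):
            s = i * (2_000_000 - 3000) // 29
            rows.append(
                {
                    "maize1_gene": f"a{i}", "maize2_gene": f"b{i}", "status": "pair",
                    "m1_chrom": "c1", "m2_chrom": "d1",
                    "m1_start": s, "m1_end": s + 3000,
                    "m2_start": s, "m2_end": s + 3000,
                    "region_m1": "arm", "region_m2": "arm",
                }
            )
        table = pd.DataFrame(rows)
        table, blocks = frac.build_blocks(table)
        tes = pd.DataFrame(
            {
                "chrom": ["c1", "c1", "d1"],
                "start": [10_000, 500_000, 100_000],
                "end": [110_000, 550_000, 150_000],
                "te_class": ["LTR", "DNA", "LTR"],
            }
        )
        maps = {
            "c1": RecombinationMap([0, 2_000_000], [0.0, 4.0]),
            "d1": RecombinationMap([0, 2_000_000], [0.0, 1.0]),
        }
        stats = frac.block_stats(blocks, table, tes, maps)
        b = stats.iloc[0]
        assert b["m1_size_mb"] == pytest.approx(2.0)
        assert b["m1_gene_density"] == pytest.approx(15.0)
        assert b["m1_te_mb"] == pytest.approx(0.15)
        assert b["m1_te_mb_LTR"] == pytest.approx(0.1)
        assert b["m2_te_mb"] == pytest.approx(0.05)
        assert b["m1_recomb"] == pytest.approx(2.0)
        assert b["m2_recomb"] == pytest.approx(0.5)

    def test_no_te_overlap_is_zero(self):
        table, blocks = frac.build_blocks(synth_table([("c1", "d1", 6)]))
        tes = pd.DataFrame(
            {"chrom": ["cX"], "start": [0], "end": [1000], "te_class": ["LTR"]}
        )
        stats = frac.block_stats(blocks, table, tes)
        assert stats["m1_te_mb"].iloc[0] == 0.0


class TestConservation:
    def test_gene_bookkeeping_is_consistent(self, toy_pipeline):
        out_dir, summary = toy_pipeline
        table = pd.read_csv(out_dir / "syntelogs_annotated.tsv", sep="\t")
        n_pairs = (table["status"] == "pair").sum()
        n_s1 = (table["status"] == "singleton_m1").sum()
        n_s2 = (table["status"] == "singleton_m2").sum()
        retained = table["maize1_gene"].notna().sum() + table["maize2_gene"].notna().sum()
        assert 2 * n_pairs + n_s1 + n_s2 == retained

    def test_biased_loss_produces_more_m1_singletons(self, toy_pipeline):
        _, summary = toy_pipeline
        r = summary["singleton_wgd_ratios"]
        # loss_prob(maize2) > loss_prob(maize1) everywhere in the generator
        assert r["maize1_arm"]["singletons"] > r["maize2_arm"]["singletons"]
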