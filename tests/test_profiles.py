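import numpy as np
import pandas as pd
import pytest

from subfrac import profiles as prof
from subfrac.tracks import SignalTrack


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


ONE_GENE = genes_frame([("c1", 10_000, 14_000, "+")])


class TestGeometry:
    def test_flank_window_counts(self):
        up, down = prof.flank_windows(
            {"chrom": "c1", "start": 10_000, "end": 14_000, "strand": "+"}, "sliding"
        )
        assert up.shape == (191, 2) and down.shape == (191, 2)
        assert up[0].tolist() == [8_000, 8_100]
        assert up[-1].tolist() == [9_900, 10_000]
        assert down[0].tolist() == [14_000, 14_100]

    def test_minus_strand_windows_mirror(self):
        up, down = prof.flank_windows(
            {"chrom": "c1", "start": 10_000, "end": 14_000, "strand": "-"}, "sliding"
        )
        assert up[0].tolist() == [15_900, 16_000]  # farthest upstream of TSS=end
        assert down[0].tolist() == [9_900, 10_000]

    def test_body_bins_equal_size_arithmetic(self):
        bins = prof.body_bins({"start": 0, "end": 4000, "strand": "+"})
        assert bins.shape == (40, 2)
        assert bins[0].tolist() == [0, 100]
        assert bins[39].tolist() == [3900, 4000]

    def test_short_gene_has_no_body_bins(self):
        assert prof.body_bins({"start": 0, "end": 30, "strand": "+"}) is None


class TestNearestTeDistance:
    def test_overlap_is_zero(self):
        assert prof.nearest_te_distance(100, 200, np.array([150]), np.array([300])) == 0

    def test_gap_distance(self):
        assert prof.nearest_te_distance(1000, 2000, np.array([0]), np.array([500])) == 500

    def test_minimum_of_both_sides(self):
        d = prof.nearest_te_distance(
            1000, 2000, np.array([0, 2200]), np.array([700, 2500])
        )
        assert d == 200

    def test_no_te_is_na(self):
        assert np.isnan(prof.nearest_te_distance(0, 10, np.array([]), np.array([])))


class TestTeProportion:
    def test_no_tes_gives_zero_profile(self):
        tes = pd.DataFrame(columns=["chrom", "start", "end"])
        p = prof.te_proportion_profile(ONE_GENE, tes)
        assert np.all(p.upstream == 0) and np.all(p.downstream == 0)

    def test_fully_covered_flank(self):
        tes = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [20_000]})
        p = prof.te_proportion_profile(ONE_GENE, tes)
        assert np.allclose(p.upstream, 1.0) and np.allclose(p.downstream, 1.0)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            prof.te_proportion_profile(ONE_GENE.iloc[:0], pd.DataFrame())


def sirna_track(rows, library_total):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "count"])
    return SignalTrack(df, "sirna", library_total=library_total)


class TestSirna:
    def test_tp10m_normalisation(self):
        # 12 reads in one window, library 6e6 -> 20 TP10M
        track = sirna_track([("c1", 8_005, 12)], library_total=6_000_000)
        p = prof.sirna_profile(track, ONE_GENE)
        assert p.upstream[0] == pytest.approx(12 * 1e7 / 6e6)

    def test_empty_track_gives_zero_profile(self):
        track = sirna_track([("c2", 5, 3)], library_total=1_000)
        p = prof.sirna_profile(track, ONE_GENE)
        assert np.all(p.upstream == 0) and np.all(p.downstream == 0)

    def test_tp10m_linear_in_counts(self):
        t1 = sirna_track([("c1", 8_005, 5)], library_total=1e6)
        t2 = sirna_track([("c1", 8_005, 15)], library_total=1e6)
        p1 = prof.sirna_profile(t1, ONE_GENE)
        p2 = prof.sirna_profile(t2, ONE_GENE)
        assert np.allclose(p2.upstream, 3 * p1.upstream)

    def test_missing_library_total_rejected(self):
        df = pd.DataFrame([("c1", 1, 1)], columns=["chrom", "pos", "count"])
        with pytest.raises(ValueError):
            prof.sirna_profile(SignalTrack(df, "sirna"), ONE_GENE)


def meth_track(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "context", "meth", "total"])
    return SignalTrack(df, "methylation")


class TestMethylation:
    def test_weighted_methylation_definition(self):
        # 4 methylated / 16 total calls in one 50 bp window -> 0.25
        track = meth_track(
            [("c1", 8_010, "CHH", 1, 4), ("c1", 8_020, "CHH", 3, 12)]
        )
        p = prof.methylation_profile(track, ONE_GENE, "CHH")
        assert p.upstream[0] == pytest.approx(0.25)

    def test_fully_methylated_window(self):
        track = meth_track([("c1", 8_010, "CHH", 9, 9)])
        p = prof.methylation_profile(track, ONE_GENE, "CHH")
        assert p.upstream[0] == 1.0

    def test_zero_coverage_windows_excluded_from_means(self):
        track = meth_track([("c1", 8_010, "CHH", 1, 2)])
        p = prof.methylation_profile(track, ONE_GENE, "CHH")
        assert p.n_upstream[0] == 1
        assert p.n_upstream[1] == 0  # no cytosines there: not a zero, an absence
        assert p.upstream[1] == 0.0

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            prof.methylation_profile(meth_track([]), ONE_GENE, "CWW")

    def test_levels_stay_in_unit_interval(self, toy_dataset):
        data_dir, _ = toy_dataset
        from subfrac import io

        track = io.read_methylation_track(data_dir / "tracks" / "methylation.tsv")
        genes = io.read_gff3(data_dir / "genes.gff3").head(40)
        p = prof.methylation_profile(track, genes, "CHH")
        for arr in (p.upstream, p.body, p.downstream):
            assert np.all((arr >= 0) & (arr <= 1))


def histone_track(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "treat", "input"])
    return SignalTrack(df, "histone")


class TestHistone:
    def test_equal_treat_input_is_flat_zero(self):
        t = histone_track([("c1", 8_050, 5, 5), ("c1", 12_000, 3, 3)])
        p = prof.histone_profile(t, t, ONE_GENE)
        assert np.all(p.upstream == 0) and np.all(p.body == 0)

    def test_log2_pseudocount_formula(self):
        t = histone_track([("c1", 8_050, 7, 3)])
        p = prof.histone_profile(t, t, ONE_GENE)
        assert p.upstream[0] == pytest.approx(1.0)  # log2(8/4)

    def test_zero_counts_give_zero_signal(self):
        t = histone_track([("c1", 8_050, 0, 0)])
        p = prof.histone_profile(t, t, ONE_GENE)
        assert np.all(p.upstream == 0)

    def test_mismatched_chromosomes_rejected(self):
        t = histone_track([("c1", 1, 1, 1)])
        other = histone_track([("c9", 1, 1, 1)])
        with pytest.raises(ValueError):
            prof.histone_profile(t, other, ONE_GENE)


class TestStrandSymmetry:
    def test_strand_flip_preserves_symmetric_track_profile(self):
        """A track symmetric around each gene's midpoint yields the same
        aggregate profile when every gene's strand is flipped."""
        genes_plus = genes_frame([("c1", 10_000, 14_000, "+"), ("c1", 50_000, 54_000, "+")])
        genes_minus = genes_plus.assign(strand="-")
        rng = np.random.default_rng(3)
        rows = []
        for start, end in ((10_000, 14_000), (50_000, 54_000)):
            for p in range(start - 2500, start + 2000, 7):
                v = int(rng.integers(0, 5))
                rows.append(("c1", p, v))
                # reflect each point through the gene's base-level centre
                rows.append(("c1", start + end - 1 - p, v))
        track = sirna_track(rows, library_total=1e6)
        p_plus = prof.sirna_profile(track, genes_plus)
        p_minus = prof.sirna_profile(track, genes_minus)
        assert np.allclose(p_plus.upstream, p_minus.upstream, atol=1e-9)
        assert np.allclose(p_plus.downstream, p_minus.downstream, atol=1e-9)
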