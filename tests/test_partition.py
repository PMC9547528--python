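import json

import numpy as np
import pandas as pd
import pytest

from subfrac import partition as part


def make_track(n_windows, recomb, repeat, chrom="chr1"):
    starts = np.arange(n_windows) * part.STEP
    return pd.DataFrame(
        {
            "chrom": chrom,
            "window_start": starts,
            "window_end": starts + part.WINDOW,
            "gene_density": 10.0,
            "repeat_length": repeat,
            "recombination": recomb,
        }
    )


class TestWindowStats:
    def test_window_count_follows_sliding_arithmetic(self):
        # 10 Mb -> starts at 0, 0.5, ..., 9 Mb
        track = part.window_stats(np.array([]), np.empty((0, 2)), 10_000_000)
        assert len(track) == 19
        assert track["window_start"].iloc[-1] == 9_000_000

    def test_empty_inputs_give_zero_densities(self):
        track = part.window_stats(np.array([]), np.empty((0, 2)), 3_000_000)
        assert (track["gene_density"] == 0).all()
        assert (track["repeat_length"] == 0).all()

    def test_fully_repeat_covered_window(self):
        track = part.window_stats(
            np.array([100.0]), np.array([[0, 2_000_000]]), 2_000_000
        )
        assert track["repeat_length"].iloc[0] == 1.0
        assert track["gene_density"].iloc[0] == 1.0  # one gene start per Mb window

    def test_gene_counted_by_start_position(self):
        # gene starting at 999,999 belongs to window [0, 1 Mb) but not [0.5, 1.5)
        track = part.window_stats(np.array([999_999.0]), np.empty((0, 2)), 2_000_000)
        assert track["gene_density"].iloc[0] == 1.0
        assert track["gene_density"].iloc[1] == 1.0  # start also within [0.5, 1.5)
        assert track["gene_density"].iloc[2] == 0.0

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError):
            part.window_stats(np.array([-5.0]), np.empty((0, 2)), 1_000_000)


class TestRecombinationMap:
    def test_constant_rate(self):
        m = part.RecombinationMap([0, 2_000_000], [0.0, 4.0])
        assert m.rate_at(1_000_000)[0] == pytest.approx(2.0)
        assert m.interval_rate(0, 2_000_000) == pytest.approx(2.0)

    def test_zero_delta_cm_is_suppressed_recombination(self):
        m = part.RecombinationMap([0, 1_000_000, 2_000_000], [1.0, 1.0, 2.0])
        assert m.rate_at(500_000)[0] == 0.0

    def test_piecewise_slope(self):
        m = part.RecombinationMap([0, 1_000_000, 3_000_000], [0.0, 1.0, 1.5])
        assert m.rate_at(2_000_000)[0] == pytest.approx(0.25)

    def test_decreasing_cm_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            part.RecombinationMap([0, 1_000_000], [1.0, 0.5])


class TestSegment:
    def test_low_recombination_block_becomes_peri(self):
        recomb = np.full(19, 5.0)
        recomb[6:13] = 0.1
        repeat = np.full(19, 0.2)
        repeat[6:13] = 0.8
        track = make_track(19, recomb, repeat)
        p = part.segment(
            track, (4_500_000, 5_500_000), chrom_length=10_000_000, t_min=0.5
        )
        # block of qualifying windows spans starts 3-6.5 Mb once smoothing
        # is accounted for; check the recovered peri brackets the centromere
        # and stays within the low-recombination region's outer windows
        assert p.peri[0] <= 4_500_000 and p.peri[1] >= 5_500_000
        assert p.peri[0] >= 2_000_000 and p.peri[1] <= 8_000_000
        assert p.arm1[0] == 0 and p.arm2[1] == 10_000_000

    def test_thresholds_admitting_everything_warn_whole_chromosome(self):
        track = make_track(19, np.zeros(19), np.full(19, 0.9))
        with pytest.warns(UserWarning, match="whole chromosome"):
            p = part.segment(
                track, (4_500_000, 5_500_000), chrom_length=10_000_000, t_min=0.5
            )
        assert p.peri == (0, 10_000_000)
        assert p.arm1 == (0, 0) and p.arm2 == (10_000_000, 10_000_000)

    def test_centromere_outside_chromosome_rejected(self):
        track = make_track(19, np.full(19, 5.0), np.full(19, 0.2))
        with pytest.raises(part.PartitionError):
            part.segment(track, (9_000_000, 12_000_000), chrom_length=10_000_000)

    def test_partition_tiles_and_contains_centromere(self):
        recomb = np.full(19, 5.0)
        recomb[6:13] = 0.0
        repeat = np.full(19, 0.1)
        repeat[6:13] = 0.9
        p = part.segment(
            make_track(19, recomb, repeat),
            (4_700_000, 5_300_000),
            chrom_length=10_000_000,
            t_min=0.5,
        )
        assert p.arm1[1] == p.peri[0] and p.peri[1] == p.arm2[0]
        assert p.peri[0] <= 4_700_000 and 5_300_000 <= p.peri[1]


class TestClassify:
    part_10mb = part.partition_from_boundaries("chr1", 10_000_000, (3_000_000, 7_000_000))

    def test_arm_and_peri_midpoints(self):
        parts = {"chr1": self.part_10mb}
        assert part.classify_region(100, 200, "chr1", parts) == "arm"
        assert part.classify_region(4_000_000, 4_001_000, "chr1", parts) == "peri"

    def test_boundary_feature_classified_by_midpoint(self):
        parts = {"chr1": self.part_10mb}
        # straddles the arm1/peri boundary, midpoint inside peri
        assert part.classify_region(2_900_000, 3_300_000, "chr1", parts) == "peri"
        assert part.classify_region(2_700_000, 3_100_000, "chr1", parts) == "arm"

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(part.PartitionError):
            part.classify_region(0, 10, "chrX", {"chr1": self.part_10mb})


class TestSyntheticRecovery:
    def test_peri_fraction_recovered(self, toy_pipeline):
        """Planted pericentromere (40% of 10 Mb) is recovered to within two
        1 Mb windows on every chromosome."""
        _, summary = toy_pipeline
        for chrom, rec in summary["partition"].items():
            peri_len = rec["peri"][1] - rec["peri"][0]
            assert abs(peri_len - 0.4 * rec["length"]) <= 2_000_000, chrom

    def test_recombination_lower_in_peri(self, toy_dataset):
        data_dir, _ = toy_dataset
        markers = pd.read_csv(data_dir / "markers.tsv", sep="\t")
        with open(data_dir / "truth.json") as fh:
            b0, b1 = json.load(fh)["peri_band"]
        for chrom, g in markers.groupby("chrom"):
            m = part.RecombinationMap(g["bp"].to_numpy(), g["cM"].to_numpy())
            arm = m.interval_rate(0, b0)
            peri = m.interval_rate(b0, b1)
            assert peri < arm
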