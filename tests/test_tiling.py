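import numpy as np
import pandas as pd
import pytest

from tilemeth.io_formats import CPG_COLUMNS
from tilemeth.tiling import drop_chromosomes, filter_by_coverage, tile_counts


def sites(*rows):
    """rows of (chrom, pos, strand, n_meth, n_unmeth)"""
    return pd.DataFrame(list(rows), columns=CPG_COLUMNS)


ONE_GROUP = {"s1": "female", "s2": "male"}


class TestTileCounts:
    def test_counts_are_additive_within_tile(self):
        per_sample = {
            "s1": sites(("chr1", 5, ".", 3, 1), ("chr1", 99, ".", 2, 2)),
            "s2": sites(("chr1", 5, ".", 1, 1), ("chr1", 99, ".", 1, 0)),
        }
        tm = tile_counts(per_sample, ONE_GROUP, tile_size=100)
        assert tm.tile_ids() == [("chr1", 0, 100)]
        assert tm.meth[0].tolist() == [5, 2]
        assert tm.total[0].tolist() == [8, 3]

    def test_tile_boundary_is_half_open(self):
        per_sample = {"s1": sites(("chr1", 100, ".", 1, 1)), "s2": sites(("chr1", 100, ".", 1, 1))}
        tm = tile_counts(per_sample, ONE_GROUP, tile_size=100)
        assert tm.tile_ids() == [("chr1", 100, 200)]

    def test_total_reads_conserved(self, small_sim):
        samples, _, _ = small_sim
        from tilemeth import group_labels

        tm = tile_counts(samples, group_labels(samples))
        for j, sid in enumerate(tm.samples):
            df = samples[sid]
            assert tm.total[:, j].sum() == (df["n_meth"] + df["n_unmeth"]).sum()
            assert tm.meth[:, j].sum() == df["n_meth"].sum()

    def test_minus_strand_pooled_with_plus_partner(self):
        per_sample = {
            "s1": sites(("chr1", 99, "+", 2, 0), ("chr1", 100, "-", 0, 3)),
            "s2": sites(("chr1", 99, "+", 1, 0), ("chr1", 100, "-", 1, 0)),
        }
        tm = tile_counts(per_sample, ONE_GROUP, tile_size=100, merge_strands=True)
        # the minus-strand cytosine at 100 belongs to the CpG dyad at 99
        assert tm.tile_ids() == [("chr1", 0, 100)]
        assert tm.total[0].tolist() == [5, 2]
        raw = tile_counts(per_sample, ONE_GROUP, tile_size=100, merge_strands=False)
        assert raw.tile_ids() == [("chr1", 0, 100), ("chr1", 100, 200)]

    def test_empty_sample_rejected_by_name(self):
        per_sample = {"s1": sites(("chr1", 5, ".", 1, 1)), "s2": sites()}
        with pytest.raises(ValueError, match="s2"):
            tile_counts(per_sample, ONE_GROUP)

    def test_retiling_is_identity(self, small_matrix):
        # feed each tile back as a single pooled site: same matrix comes out
        tm = small_matrix
        resites = {
            sid: pd.DataFrame(
                {
                    "chrom": tm.tiles["chrom"],
                    "pos": tm.tiles["start"],
                    "strand": ".",
                    "n_meth": tm.meth[:, j],
                    "n_unmeth": tm.total[:, j] - tm.meth[:, j],
                }
            )
            for j, sid in enumerate(tm.samples)
        }
        again = tile_counts(resites, tm.groups, tile_size=tm.tile_size)
        pd.testing.assert_frame_equal(again.tiles, tm.tiles)
        assert np.array_equal(again.meth, tm.meth)
        assert np.array_equal(again.total, tm.total)

    def test_tile_starts_grid_aligned(self, small_matrix):
        assert (small_matrix.tiles["start"] % small_matrix.tile_size == 0).all()


class TestCoverageFilter:
    def test_minimum_is_strictly_greater_than(self):
        per_sample = {
            "s1": sites(("chr1", 5, ".", 5, 5), ("chr1", 205, ".", 30, 30)),
            "s2": sites(("chr1", 5, ".", 10, 10), ("chr1", 205, ".", 20, 20)),
        }
        tm = tile_counts(per_sample, ONE_GROUP)
        kept = filter_by_coverage(tm, min_coverage=10, max_percentile=100)
        assert kept.tile_ids() == [("chr1", 200, 300)]  # the 10-read tile is out
        inclusive = filter_by_coverage(tm, min_coverage=10, max_percentile=100, inclusive_min=True)
        assert inclusive.n_tiles == 2

    def test_degenerate_equal_coverage_loses_nothing_to_percentile(self):
        rows_a = [("chr1", p, ".", 25, 25) for p in range(0, 1000, 100)]
        per_sample = {"s1": sites(*rows_a), "s2": sites(*rows_a)}
        tm = tile_counts(per_sample, ONE_GROUP)
        kept = filter_by_coverage(tm, min_coverage=10, max_percentile=99.8)
        assert kept.n_tiles == tm.n_tiles == 10

    def test_matches_bruteforce_predicate(self, small_matrix):
        min_cov, pct = 10, 99.8
        kept = filter_by_coverage(small_matrix, min_coverage=min_cov, max_percentile=pct)
        cuts = [
            np.percentile(col[col > 0], pct)
            for col in small_matrix.total.T
        ]
        expected = []
        for i in range(small_matrix.n_tiles):
            ok = all(
                small_matrix.total[i, j] > min_cov and small_matrix.total[i, j] <= cuts[j]
                for j in range(small_matrix.n_samples)
            )
            if ok:
                expected.append(small_matrix.tile_ids()[i])
        assert kept.tile_ids() == expected

    def test_recorded_percentile_cut_matches_hand_computation(self):
        # 10 tiles, one sample pair; 99.8th percentile by linear interpolation
        covs = [12, 14, 16, 18, 20, 22, 24, 26, 28, 300]
        rows = [("chr1", 100 * i + 5, ".", c // 2, c - c // 2) for i, c in enumerate(covs)]
        per_sample = {"s1": sites(*rows), "s2": sites(*rows)}
        tm = tile_counts(per_sample, ONE_GROUP)
        kept = filter_by_coverage(tm, min_coverage=0, max_percentile=90)
        # hand-computed: sorted covs, rank 0.9*(10-1)=8.1 -> 28 + 0.1*(300-28)
        expected_cut = 28 + 0.1 * (300 - 28)
        rec = kept.provenance["filters"][-1]["percentile_cuts"]["s1"]
        assert rec == pytest.approx(expected_cut)
        assert kept.n_tiles == 9  # only the 300x pileup removed

    def test_monotone_in_min_coverage(self, small_matrix):
        sizes = []
        for mc in (0, 5, 10, 20, 40):
            try:
                sizes.append(filter_by_coverage(small_matrix, min_coverage=mc).n_tiles)
            except ValueError:
                sizes.append(0)
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_arguments_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            filter_by_coverage(small_matrix, min_coverage=-1)
        with pytest.raises(ValueError, match="review"):
            filter_by_coverage(small_matrix, min_coverage=10**9)


class TestDropChromosomes:
    def test_drop_removes_exactly_named_chromosomes(self, small_matrix):
        before = small_matrix.n_tiles
        on_chr2 = (small_matrix.tiles["chrom"] == "chr2").sum()
        out = drop_chromosomes(small_matrix, {"chr2"})
        assert set(out.tiles["chrom"]) == {"chr1"}
        assert out.n_tiles == before - on_chr2

    def test_absent_chromosome_is_noop(self, small_matrix):
        out = drop_chromosomes(small_matrix, {"chrY"})
        assert out.n_tiles == small_matrix.n_tiles

    def test_empty_set_is_identity(self, small_matrix):
        out = drop_chromosomes(small_matrix, set())
        assert out is small_matrix
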