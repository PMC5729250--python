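import numpy as np
import pandas as pd
import pytest

from tilemeth.annotate import (
    AnnotationScheme,
    annotate_tiles,
    direction_bias,
    overlap_dmt_sets,
    overlaps_any,
    permutation_enrichment,
)


def iv(*rows):
    return pd.DataFrame(list(rows), columns=["chrom", "start", "end"])


def tiles_df(tile_ids):
    return pd.DataFrame(tile_ids, columns=["chrom", "start", "end"])


def grid(n, chrom="chr1", size=100):
    starts = np.arange(n) * size
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + size})


class TestOverlapsAny:
    def test_matches_bruteforce_on_random_intervals(self, rng):
        tiles = grid(300)
        starts = rng.integers(0, 30_000, size=40)
        peaks = iv(*[("chr1", int(s), int(s + rng.integers(1, 500))) for s in starts])
        got = overlaps_any(tiles, peaks)
        expect = [
            any(ps < te and pe > ts for ps, pe in zip(peaks["start"], peaks["end"]))
            for ts, te in zip(tiles["start"], tiles["end"])
        ]
        assert got.tolist() == expect

    def test_touching_intervals_do_not_overlap(self):
        tiles = iv(("chr1", 100, 200))
        assert not overlaps_any(tiles, iv(("chr1", 0, 100))).any()
        assert not overlaps_any(tiles, iv(("chr1", 200, 300))).any()
        assert overlaps_any(tiles, iv(("chr1", 199, 300))).all()


class TestAnnotateTiles:
    def scheme(self):
        islands = iv(("chr1", 10_000, 11_000))
        return AnnotationScheme.cpg_island_scheme(islands, shore_flank=2000)

    def test_tile_inside_island(self):
        labels, _ = annotate_tiles(tiles_df([("chr1", 10_200, 10_300)]), self.scheme())
        assert labels.tolist() == ["cpg_island"]

    def test_tile_1500bp_from_island_edge_is_shore(self):
        labels, _ = annotate_tiles(tiles_df([("chr1", 12_500, 12_600)]), self.scheme())
        assert labels.tolist() == ["shore"]

    def test_far_tile_is_open_sea(self):
        labels, _ = annotate_tiles(tiles_df([("chr1", 50_000, 50_100)]), self.scheme())
        assert labels.tolist() == ["open_sea"]

    def test_fractions_partition_to_one(self, rng):
        tiles = grid(500)
        _, fractions = annotate_tiles(tiles, self.scheme())
        assert fractions.sum() == pytest.approx(1.0)

    def test_precedence_is_first_match(self):
        scheme = AnnotationScheme(
            features={"promoter": iv(("chr1", 0, 1000)), "exon": iv(("chr1", 0, 1000))},
        )
        labels, _ = annotate_tiles(tiles_df([("chr1", 100, 200)]), scheme)
        assert labels.tolist() == ["promoter"]

    def test_empty_scheme_rejected(self):
        with pytest.raises(ValueError):
            AnnotationScheme(features={})


class TestDirectionBias:
    def calls(self, directions, chroms=None):
        n = len(directions)
        return pd.DataFrame(
            {
                "chrom": chroms or ["chr1"] * n,
                "start": np.arange(n) * 100,
                "end": np.arange(n) * 100 + 100,
                "direction": directions,
            }
        )

    def test_all_female_hyper(self):
        bias = direction_bias(self.calls(["female-hyper"] * 4))
        assert (bias["fraction_female_hyper"] == 1.0).all()

    def test_even_split(self):
        bias = direction_bias(self.calls(["female-hyper", "male-hyper"] * 3))
        overall = bias.loc[bias["chrom"] == "overall", "fraction_female_hyper"].iloc[0]
        assert overall == pytest.approx(0.5)

    def test_overall_is_count_weighted_mean(self):
        directions = ["female-hyper"] * 5 + ["male-hyper"] * 3
        chroms = ["chr1"] * 2 + ["chr2"] * 6
        bias = direction_bias(self.calls(directions, chroms))
        per_chrom = bias[bias["chrom"] != "overall"]
        weighted = (per_chrom["fraction_female_hyper"] * per_chrom["n_calls"]).sum()
        overall = bias.loc[bias["chrom"] == "overall"].iloc[0]
        assert weighted / per_chrom["n_calls"].sum() == pytest.approx(
            overall["fraction_female_hyper"]
        )

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            direction_bias(self.calls([]).iloc[:0])


class TestVennOverlap:
    def test_identical_sets(self):
        a = {("chr1", 0, 100), ("chr1", 200, 300)}
        regions = overlap_dmt_sets({"A": a, "B": set(a)})
        assert regions[("A", "B")] == 2
        assert regions[("A",)] == 0 and regions[("B",)] == 0

    def test_disjoint_sets(self):
        regions = overlap_dmt_sets(
            {"A": {("chr1", 0, 100)}, "B": {("chr2", 0, 100)}}
        )
        assert regions[("A", "B")] == 0
        assert regions[("A",)] == regions[("B",)] == 1

    def test_three_sets_match_bruteforce(self, rng):
        universe = [("chr1", int(s) * 100, int(s) * 100 + 100) for s in range(1000)]
        sets = {
            name: {universe[i] for i in rng.choice(1000, size=rng.integers(50, 300), replace=False)}
            for name in ("liver", "brain", "heart")
        }
        regions = overlap_dmt_sets(sets)
        names = list(sets)
        expected = {}
        for t in {t for s in sets.values() for t in s}:
            members = tuple(sorted(n for n in names if t in sets[n]))
            expected[members] = expected.get(members, 0) + 1
        for combo, count in regions.items():
            assert count == expected.get(combo, 0)

    def test_mixed_tile_sizes_rejected(self):
        with pytest.raises(ValueError, match="tile size"):
            overlap_dmt_sets({"A": {("chr1", 0, 100)}, "B": {("chr1", 0, 200)}})

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_dmt_sets({"A": {("chr1", 0, 100)}})


class TestPermutationEnrichment:
    def test_saturating_peaks_give_p_one(self):
        universe = grid(200)
        query = universe.iloc[:50]
        peaks = iv(("chr1", 0, 20_000))
        res = permutation_enrichment(query, universe, peaks, n_iter=200, seed=1)
        assert res.observed_overlap == 50
        assert (res.null_counts == 50).all()
        assert res.empirical_p == 1.0

    def test_zero_overlap_query(self):
        universe = grid(200)
        query = universe.iloc[:50]
        peaks = iv(("chr1", 10_000, 15_000))  # misses the query, hits the rest
        res = permutation_enrichment(query, universe, peaks, n_iter=500, seed=2)
        assert res.observed_overlap == 0
        assert res.empirical_p > 0.99
        assert res.depletion_p == pytest.approx(1 / 501)

    def test_planted_enrichment_reaches_floor(self):
        universe = grid(2000)
        hot = universe.iloc[:240]  # 80% of a 300-tile query will come from here
        query = pd.concat([hot, universe.iloc[1000:1060]])
        peaks = iv(("chr1", 0, 24_000), ("chr1", 150_000, 152_000))
        res = permutation_enrichment(query, universe, peaks, n_iter=2000, seed=3)
        assert res.empirical_p == pytest.approx(1 / 2001)

    def test_fixed_seed_is_bit_reproducible(self):
        universe = grid(300)
        query = universe.iloc[10:80]
        peaks = iv(("chr1", 0, 5_000))
        r1 = permutation_enrichment(query, universe, peaks, n_iter=300, seed=9)
        r2 = permutation_enrichment(query, universe, peaks, n_iter=300, seed=9)
        assert np.array_equal(r1.null_counts, r2.null_counts)
        assert r1.empirical_p == r2.empirical_p

    def test_p_never_zero_and_respects_floor(self):
        universe = grid(100)
        query = universe.iloc[:10]
        peaks = iv(("chr1", 0, 1_000))
        res = permutation_enrichment(query, universe, peaks, n_iter=50, seed=4)
        assert res.empirical_p >= 1 / 51
        assert res.depletion_p >= 1 / 51

    def test_query_outside_universe_rejected(self):
        universe = grid(100)
        rogue = iv(("chr9", 0, 100))
        with pytest.raises(ValueError, match="subset"):
            permutation_enrichment(rogue, universe, iv(("chr1", 0, 500)), n_iter=10, seed=0)
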