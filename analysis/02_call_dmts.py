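"""Tile the study's per-CpG counts into 100-bp windows, apply the coverage
filters (>10x in every sample, below each sample's 99.8th coverage
percentile), test every tile female-vs-male, and call DMTs at |diff| >= 25
points and q <= 0.01.

Reads the coverage files written by 01 when present (exercising the Bismark
reader); otherwise regenerates the same study in memory. Writes the DMT
table to results/ and the full per-tile statistics to scratch/.
"""

from common import RESULTS, SCRATCH, ensure_dirs, simulate_study, tile_and_call

from tilemeth import group_labels, read_coverage_file, write_dmt_table
from tilemeth.diffmeth import call_dmts
from tilemeth.tiling import filter_by_coverage, tile_counts


def main():
    ensure_dirs()
    simdir = SCRATCH / "simdata"
    cov_files = sorted(simdir.glob("*.cov")) if simdir.exists() else []
    cfg, samples_mem, truth, peaks = simulate_study()
    if cov_files:
        samples = {p.stem: read_coverage_file(p, "bismark-coverage") for p in cov_files}
        tm = filter_by_coverage(tile_counts(samples, group_labels(samples)))
        calls, stats = call_dmts(tm)
    else:
        tm, calls, stats = tile_and_call(samples_mem)

    write_dmt_table(calls, RESULTS / "dmt_calls.tsv")
    stats.to_csv(SCRATCH / "tile_statistics.tsv", sep="\t", index=False)

    truth_ids = set(map(tuple, truth.table[["chrom", "start", "end"]].itertuples(index=False)))
    call_ids = set(map(tuple, calls[["chrom", "start", "end"]].itertuples(index=False)))
    print(f"retained {tm.n_tiles} tiles after coverage filtering")
    print(f"called {len(calls)} DMTs (|diff| >= 25 points, q <= 0.01)")
    print(f"recovered {len(call_ids & truth_ids)}/{len(truth_ids)} planted tiles, "
          f"{len(call_ids - truth_ids)} spurious calls")
    print(f"wrote {RESULTS/'dmt_calls.tsv'}")


if __name__ == "__main__":
    main()
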