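"""Directional bias and genomic annotation of the study's DMTs.

Reports, per chromosome and overall, the fraction of DMTs hypermethylated
in females, and classifies the retained tiles and the DMTs against the
generator's CpG-island grid (island / shore / open sea).
"""

import pandas as pd

from common import RESULTS, ensure_dirs, simulate_study, tile_and_call

from tilemeth import AnnotationScheme, annotate_tiles, direction_bias
from tilemeth.simulate import island_intervals


def main():
    ensure_dirs()
    cfg, samples, truth, _ = simulate_study()
    tm, calls, _ = tile_and_call(samples)

    bias = direction_bias(calls)
    bias.to_csv(RESULTS / "direction_bias.tsv", sep="\t", index=False)
    overall = bias.loc[bias["chrom"] == "overall"].iloc[0]
    print(f"{overall['n_calls']:.0f} DMTs, "
          f"{overall['fraction_female_hyper']:.1%} hypermethylated in females")
    for row in bias[bias["chrom"] != "overall"].itertuples(index=False):
        print(f"  {row.chrom}: {row.fraction_female_hyper:.1%} female-hyper "
              f"({row.n_calls} DMTs)")

    islands = pd.concat(
        [
            pd.DataFrame(island_intervals(length, cfg), columns=["start", "end"]).assign(chrom=name)
            for name, length in cfg.chromosomes
        ]
    )[["chrom", "start", "end"]]
    scheme = AnnotationScheme.cpg_island_scheme(islands, shore_flank=2000)
    _, frac_universe = annotate_tiles(tm.tiles, scheme)
    _, frac_dmt = annotate_tiles(calls[["chrom", "start", "end"]], scheme)
    table = pd.DataFrame({"all_tiles": frac_universe, "dmts": frac_dmt})
    table.to_csv(RESULTS / "island_annotation.tsv", sep="\t")
    print("CpG-island annotation (fraction of tiles):")
    print(table.round(3).to_string())
    print(f"wrote {RESULTS/'direction_bias.tsv'} and {RESULTS/'island_annotation.tsv'}")


if __name__ == "__main__":
    main()
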