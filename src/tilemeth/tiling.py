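"""Aggregation of per-CpG counts into fixed grid-aligned tiles, plus the
coverage filters applied before differential testing.

Tiles are grid-aligned windows of ``tile_size`` bp (start ≡ 0 mod tile_size),
not sliding windows, matching the step-equals-window tiling used by methylKit.
A CpG at 0-based position ``p`` belongs to the tile ``floor(p / tile_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TILE_KEYS = ["chrom", "start", "end"]


@dataclass
class TileMatrix:
    """Fixed genomic tiles × samples with pooled methylation counts.

    Attributes
    ----------
    tiles : DataFrame with columns chrom, start, end (0-based half-open).
    samples : ordered sample identifiers (column order of the count arrays).
    groups : mapping sample id -> group label (e.g. "female"/"male").
    meth, total : int arrays of shape (n_tiles, n_samples); methylated and
        total read counts pooled over the CpGs of each tile.
    tile_size : tile width in bp.
    provenance : record of the construction parameters and filters applied.
    """

    tiles: pd.DataFrame
    samples: list
    groups: dict
    meth: np.ndarray
    total: np.ndarray
    tile_size: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if self.groups[s] == group])

    def tile_ids(self) -> list:
        return list(zip(self.tiles["chrom"], self.tiles["start"], self.tiles["end"]))

    def to_frame(self) -> pd.DataFrame:
        """Wide audit table: tile coordinates plus per-sample count pairs."""
        out = self.tiles.reset_index(drop=True).copy()
        for j, s in enumerate(self.samples):
            out[f"{s}.n_meth"] = self.meth[:, j]
            out[f"{s}.n_total"] = self.total[:, j]
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tile_counts(
    sites_per_sample: dict,
    groups: dict,
    tile_size: int = 100,
    merge_strands: bool = True,
) -> TileMatrix:
    """Pool per-CpG counts of every sample into a shared tile grid.

    ``sites_per_sample`` maps sample id -> CpG frame (io_formats schema).
    With ``merge_strands`` (default), a minus-strand cytosine at position p
    is pooled with its plus-strand partner at p-1 before tiling, so both
    strands of a CpG dyad contribute to one destranded unit; strand-unknown
    positions ('.') are left where they are. The tile universe is the union
    of covered tiles over all samples; a tile a sample does not cover gets
    zero counts there (removed later by the coverage filter).
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1, got {tile_size}")
    per_sample = []
    sample_ids = list(sites_per_sample)
    for sid in sample_ids:
        df = sites_per_sample[sid]
        if len(df) == 0:
            raise ValueError(f"sample {sid!r} has no CpGs")
        pos = df["pos"].to_numpy(copy=True)
        if merge_strands:
            pos = np.where(df["strand"].to_numpy() == "-", pos - 1, pos)
        agg = (
            pd.DataFrame(
                {
                    "chrom": df["chrom"].to_numpy(),
                    "start": (pos // tile_size) * tile_size,
                    "n_meth": df["n_meth"].to_numpy(),
                    "n_total": df["n_meth"].to_numpy() + df["n_unmeth"].to_numpy(),
                }
            )
            .groupby(["chrom", "start"], sort=False, as_index=False)
            .sum()
        )
        agg["sample"] = sid
        per_sample.append(agg)
    longf = pd.concat(per_sample, ignore_index=True)
    meth_w = longf.pivot_table(
        index=["chrom", "start"], columns="sample", values="n_meth", fill_value=0, aggfunc="sum"
    )
    total_w = longf.pivot_table(
        index=["chrom", "start"], columns="sample", values="n_total", fill_value=0, aggfunc="sum"
    )
    meth_w = meth_w.sort_index()[sample_ids]
    total_w = total_w.sort_index()[sample_ids]
    tiles = meth_w.index.to_frame(index=False)
    tiles["end"] = tiles["start"] + tile_size
    return TileMatrix(
        tiles=tiles[TILE_KEYS].reset_index(drop=True),
        samples=sample_ids,
        groups=dict(groups),
        meth=meth_w.to_numpy(dtype=np.int64),
        total=total_w.to_numpy(dtype=np.int64),
        tile_size=tile_size,
        provenance={"tile_size": tile_size, "merge_strands": merge_strands, "filters": []},
    )


def filter_by_coverage(
    tm: TileMatrix,
    min_coverage: int = 10,
    max_percentile: float = 99.8,
    pooled_percentile: bool = False,
    inclusive_min: bool = False,
) -> TileMatrix:
    """Apply the coverage filters: minimum depth in every sample and an upper
    percentile cut against PCR-duplicate-like pileups.

    A tile is retained iff its total count exceeds ``min_coverage`` in every
    sample (strictly, unless ``inclusive_min``) and is not strictly above the
    ``max_percentile``-th percentile cutoff in any sample (so a degenerate
    all-equal coverage distribution loses nothing to the upper cut). By default the
    cutoff is computed per sample over that sample's covered-tile coverage
    distribution; with ``pooled_percentile`` one cutoff is computed from all
    samples' covered-tile coverages pooled and applied to every sample.
    Percentiles use linear interpolation between order statistics.
    """
    if min_coverage < 0:
        raise ValueError(f"min_coverage must be >= 0, got {min_coverage}")
    if not 0 < max_percentile <= 100:
        raise ValueError(f"max_percentile must be in (0, 100], got {max_percentile}")
    total = tm.total
    if inclusive_min:
        low_ok = (total >= min_coverage).all(axis=1)
    else:
        low_ok = (total > min_coverage).all(axis=1)
    if pooled_percentile:
        pooled = total[total > 0]
        cut = float(np.percentile(pooled, max_percentile)) if pooled.size else np.inf
        cuts = [cut] * tm.n_samples
    else:
        cuts = []
        for j in range(tm.n_samples):
            col = total[:, j]
            col = col[col > 0]
            cuts.append(float(np.percentile(col, max_percentile)) if col.size else np.inf)
    high_ok = (total <= np.asarray(cuts)[None, :]).all(axis=1)
    keep = low_ok & high_ok
    if not keep.any():
        raise ValueError(
            "coverage filter removed every tile; review min_coverage="
            f"{min_coverage} / max_percentile={max_percentile}"
        )
    out = replace(
        tm,
        tiles=tm.tiles.loc[keep].reset_index(drop=True),
        meth=tm.meth[keep],
        total=tm.total[keep],
        provenance={
            **tm.provenance,
            "filters": tm.provenance.get("filters", [])
            + [
                {
                    "min_coverage": min_coverage,
                    "inclusive_min": inclusive_min,
                    "max_percentile": max_percentile,
                    "pooled_percentile": pooled_percentile,
                    "percentile_method": "linear",
                    "percentile_cuts": dict(zip(tm.samples, cuts)),
                }
            ],
        },
    )
    return out


def drop_chromosomes(tm: TileMatrix, names) -> TileMatrix:
    """Remove every tile on the named chromosomes (e.g. the sex chromosomes).

    Removing chromosomes absent from the matrix, or an empty set, is a no-op.
    """
    names = set(names)
    if not names:
        return tm
    keep = ~tm.tiles["chrom"].isin(names).to_numpy()
    return replace(
        tm,
        tiles=tm.tiles.loc[keep].reset_index(drop=True),
        meth=tm.meth[keep],
        total=tm.total[keep],
        provenance={
            **tm.provenance,
            "filters": tm.provenance.get("filters", []) + [{"dropped_chromosomes": sorted(names)}],
        },
    )
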