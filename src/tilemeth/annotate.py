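"""Genomic annotation of tiles, directional-bias summaries, cross-dataset
DMT overlap, and the permutation overlap-enrichment test against peak sets.

Overlap semantics throughout are "any overlap": a tile counts as hitting a
feature if it intersects it by at least one base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import FEMALE_HYPER


def _merge_intervals(iv: pd.DataFrame) -> dict:
    """Per-chromosome merged (start, end) arrays for fast any-overlap queries."""
    merged = {}
    for chrom, grp in iv.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        ms, me = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.asarray(ms), np.asarray(me))
    return merged


def overlaps_any(tiles: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each tile intersect >=1 interval by >=1 bp?"""
    tiles = tiles.reset_index(drop=True)
    out = np.zeros(len(tiles), dtype=bool)
    if len(intervals) == 0 or len(tiles) == 0:
        return out
    merged = _merge_intervals(intervals)
    for chrom, grp in tiles.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # last merged interval whose start < tile end; overlap iff it ends past tile start
        j = np.searchsorted(ms, ends, side="left") - 1
        hit = (j >= 0) & (me[np.maximum(j, 0)] > starts)
        out[grp.index.to_numpy()] = hit
    return out


def _expand(iv: pd.DataFrame, flank: int) -> pd.DataFrame:
    out = iv.copy()
    out["start"] = np.maximum(out["start"] - flank, 0)
    out["end"] = out["end"] + flank
    return out


@dataclass
class AnnotationScheme:
    """Ordered, exclusive tile annotation: each tile takes the label of the
    first feature set (in precedence order) it overlaps; tiles overlapping
    nothing get ``background_label``."""

    features: dict  # label -> interval frame (chrom, start, end), precedence = dict order
    background_label: str = "intergenic"
    shore_flank: int = 2000
    name: str = field(default="scheme")

    def __post_init__(self):
        if not self.features:
            raise ValueError("annotation scheme needs >=1 named interval set")

    @classmethod
    def cpg_island_scheme(cls, islands: pd.DataFrame, shore_flank: int = 2000):
        """Island / shore / open-sea partition: shores are the ``shore_flank``
        bp flanks of islands (island overlap wins by precedence)."""
        shores = _expand(islands, shore_flank)
        return cls(
            features={"cpg_island": islands, "shore": shores},
            background_label="open_sea",
            shore_flank=shore_flank,
            name="cpg_island",
        )

    @classmethod
    def genic_scheme(cls, promoters=None, exons=None, introns=None):
        feats = {}
        for label, iv in (("promoter", promoters), ("exon", exons), ("intron", introns)):
            if iv is not None:
                feats[label] = iv
        return cls(features=feats, background_label="intergenic", name="genic")


def annotate_tiles(tiles: pd.DataFrame, scheme: AnnotationScheme):
    """Assign each tile its highest-precedence overlapping feature label.

    Returns ``(labels, fractions)``: a per-tile label Series aligned to the
    input and the aggregate fraction of tiles per label (summing to 1).
    """
    tiles = tiles.reset_index(drop=True)
    labels = pd.Series(scheme.background_label, index=tiles.index, dtype=object)
    unassigned = np.ones(len(tiles), dtype=bool)
    for label, iv in scheme.features.items():
        if not unassigned.any():
            break
        hit = overlaps_any(tiles, iv) & unassigned
        labels[hit] = label
        unassigned &= ~hit
    order = list(scheme.features) + [scheme.background_label]
    fractions = labels.value_counts(normalize=True).reindex(order, fill_value=0.0)
    return labels, fractions


def direction_bias(calls: pd.DataFrame, by_chromosome: bool = True) -> pd.DataFrame:
    """Fraction of calls hypermethylated in females, per chromosome and overall.

    Mirrors the per-autosome hypermethylation bar plots: for every chromosome
    with >=1 call the fraction of female-hyper calls and the call count, plus
    an "overall" row. Requires a non-empty call set.
    """
    if len(calls) == 0:
        raise ValueError("empty call set: direction bias undefined")
    fem = (calls["direction"] == FEMALE_HYPER).astype(float)
    rows = []
    if by_chromosome:
        for chrom, grp in calls.groupby("chrom", sort=True):
            rows.append((chrom, fem[grp.index].mean(), len(grp)))
    rows.append(("overall", fem.mean(), len(calls)))
    return pd.DataFrame(rows, columns=["chrom", "fraction_female_hyper", "n_calls"])


def overlap_dmt_sets(named_sets: dict) -> dict:
    """Venn region counts over >=2 named DMT sets.

    ``named_sets`` maps set name -> iterable of tile identities
    (chrom, start, end) on a common tile grid; membership is exact identity.
    Returns every non-empty-signature region of the Venn partition keyed by
    the sorted tuple of member-set names, including zero counts.
    """
    if len(named_sets) < 2:
        raise ValueError("need >=2 named sets for an overlap")
    sets = {name: {tuple(t) for t in tiles} for name, tiles in named_sets.items()}
    sizes = {(int(t[2]) - int(t[1])) for s in sets.values() for t in s}
    if len(sizes) > 1:
        raise ValueError(f"sets mix tile sizes {sorted(sizes)}; overlap undefined")
    names = list(sets)
    regions = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(*(sets[n] for n in names if n not in combo), set())
            regions[tuple(sorted(combo))] = len(inside - outside)
    return regions


@dataclass
class EnrichmentResult:
    """Observed peak overlap of a tile set against its permutation null."""

    observed_overlap: int
    null_counts: np.ndarray
    empirical_p: float  # one-sided, enrichment
    depletion_p: float
    n_iter: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts))

    def summary(self) -> dict:
        return {
            "observed": int(self.observed_overlap),
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "empirical_p": self.empirical_p,
            "depletion_p": self.depletion_p,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def permutation_enrichment(
    query: pd.DataFrame,
    universe: pd.DataFrame,
    peaks: pd.DataFrame,
    n_iter: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test of peak overlap for a tile set against its universe.

    The observed statistic is the number of query tiles overlapping >=1 peak.
    Each iteration draws |query| tiles uniformly without replacement from the
    universe of retained tiles and recounts; the enrichment p-value is the
    add-one estimator (1 + #{null >= observed}) / (n_iter + 1), which never
    returns 0 — at 10,000 iterations the floor is just under 1e-4. The
    depletion p-value is the analogous lower tail.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    uni = universe.reset_index(drop=True)
    qset = {(c, int(s), int(e)) for c, s, e in zip(query["chrom"], query["start"], query["end"])}
    uids = list(zip(uni["chrom"], uni["start"].astype(int), uni["end"].astype(int)))
    uset = set(uids)
    if not qset <= uset:
        missing = len(qset - uset)
        raise ValueError(f"query is not a subset of the universe ({missing} tiles outside)")
    k = len(qset)
    if k > len(uni):
        raise ValueError("query larger than universe")
    hit = overlaps_any(uni[["chrom", "start", "end"]], peaks)
    qmask = np.fromiter((t in qset for t in uids), count=len(uids), dtype=bool)
    observed = int(hit[qmask].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        null[i] = hit[rng.permutation(len(uni))[:k]].sum()
    emp_p = (1 + int((null >= observed).sum())) / (n_iter + 1)
    dep_p = (1 + int((null <= observed).sum())) / (n_iter + 1)
    return EnrichmentResult(
        observed_overlap=observed,
        null_counts=null,
        empirical_p=emp_p,
        depletion_p=dep_p,
        n_iter=n_iter,
        seed=seed,
    )
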