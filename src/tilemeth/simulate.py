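"""Synthetic RRBS-like methylome generator.

Emulates the statistical structure the downstream analysis assumes, at desk
scale: isogenic replicates of two sexes, CpG positions clustered into
island-like runs, negative-binomial read depth per CpG per sample,
beta-distributed per-tile baseline methylation shared across samples, and a
configurable set of planted sex-differential tiles with a female-hyper bias
plus a constant female hypermethylation shift on designated sex chromosomes.

Reads, bisulphite conversion error and fragment selection are not simulated:
the generator emits per-CpG count tables directly, one per sample, with
identical CpG positions across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CPG_COLUMNS

FEMALE_HYPER = "female-hyper"
MALE_HYPER = "male-hyper"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic methylome.

    Defaults mirror the study design the pipeline targets: six isogenic
    replicates per sex, ~30× read depth per CpG, 100-bp analysis tiles, a
    planted sex effect of 40 percentage points at 100 tiles with an 80%
    female-hyper bias, and enhancer-like peak intervals enriched over the
    planted tiles.
    """

    n_per_group: int = 6
    chromosomes: tuple = (("chr1", 4_000_000), ("chr2", 3_000_000), ("chr3", 2_000_000))
    sex_chromosomes: tuple = ()  # names within `chromosomes` treated as X-like
    island_length: int = 1_000  # bp; CpG-island-like runs
    island_spacing: int = 20_000  # bp between island starts
    cpg_density_island: float = 20.0  # expected CpGs per kb inside islands
    cpg_density_open: float = 2.0  # scattered open-sea CpGs per kb
    cpg_cluster_per_kb: float = 0.3  # open-sea CpG clusters (fragment-like) per kb
    cpg_cluster_size: float = 3.0  # mean CpGs per open-sea cluster
    cpg_cluster_span: int = 80  # bp window of one open-sea cluster
    coverage_mean: float = 30.0  # negative-binomial depth per CpG per sample
    coverage_dispersion: float = 5.0  # NB size parameter (smaller = noisier)
    baseline_meth_alpha: float = 2.0  # beta parameters of per-tile baseline
    baseline_meth_beta: float = 2.0
    within_tile_sd: float = 0.02  # per-CpG jitter around tile baseline
    tile_size: int = 100
    n_planted_dmts: int = 100
    min_cpgs_planted: int = 3  # plant only in tiles with this much CpG support
    max_cpgs_planted: int = 4  # upper bound keeping planted tiles out of the density tail
    planted_effect: float = 40.0  # true group difference, percentage points
    female_hyper_fraction: float = 0.8
    planted_open_sea_fraction: float = 0.8  # planted DMTs placed outside islands
    x_hyper_shift: float = 30.0  # female shift on sex chromosomes, points
    n_peak_intervals: int = 200
    peak_dmt_enrichment: float = 0.8  # fraction of planted DMTs put inside peaks
    peak_length: int = 600
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0.0 <= self.female_hyper_fraction <= 1.0:
            raise ValueError("female_hyper_fraction must be in [0, 1]")
        if self.n_planted_dmts > 0 and not 0.0 < self.planted_effect <= 100.0:
            raise ValueError("planted_effect must be in (0, 100]")
        known = {name for name, _ in self.chromosomes}
        unknown = set(self.sex_chromosomes) - known
        if unknown:
            raise ValueError(f"sex_chromosomes not in chromosome list: {sorted(unknown)}")


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run.

    ``table`` holds the planted tiles (chrom, start, end, true_difference in
    signed percentage points — the realized, post-clamp female-minus-male
    difference — and direction). ``peaks`` are the planted peak intervals.
    """

    table: pd.DataFrame
    peaks: pd.DataFrame
    seed: int
    config: SimulationConfig = field(repr=False, default=None)


def island_intervals(length: int, cfg: SimulationConfig):
    """Deterministic island-like interval grid used by the generator."""
    offset = cfg.island_spacing // 2
    return [
        (s, min(s + cfg.island_length, length))
        for s in range(offset, length, cfg.island_spacing)
    ]


def _poisson_sites(rng, start: int, end: int, per_kb: float) -> np.ndarray:
    n_slots = (end - start) // 2
    n = min(rng.poisson((end - start) / 1000.0 * per_kb), n_slots)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    slots = rng.choice(n_slots, size=n, replace=False)
    return start + 2 * np.sort(slots)


def _cpg_positions(rng, length: int, cfg: SimulationConfig) -> np.ndarray:
    """CpG positions (0-based, even offsets): dense inside the island grid;
    outside, a mixture of scattered singletons and fragment-like clusters
    (the capture unit of reduced-representation libraries), so CpG-dense
    tiles also occur in the open sea."""
    segs = []  # (start, end, is_island)
    prev = 0
    for s, e in island_intervals(length, cfg):
        if s > prev:
            segs.append((prev, s, False))
        segs.append((s, e, True))
        prev = e
    if prev < length:
        segs.append((prev, length, False))
    chosen = []
    for start, end, is_island in segs:
        if is_island:
            chosen.append(_poisson_sites(rng, start, end, cfg.cpg_density_island))
            continue
        chosen.append(_poisson_sites(rng, start, end, cfg.cpg_density_open))
        n_clusters = rng.poisson((end - start) / 1000.0 * cfg.cpg_cluster_per_kb)
        for _ in range(n_clusters):
            if end - start <= cfg.cpg_cluster_span:
                continue
            c0 = int(rng.integers(start, end - cfg.cpg_cluster_span))
            size = min(1 + rng.poisson(cfg.cpg_cluster_size - 1), cfg.cpg_cluster_span // 2)
            slots = rng.choice(cfg.cpg_cluster_span // 2, size=size, replace=False)
            chosen.append(c0 + 2 * np.sort(slots))
    chosen = [c for c in chosen if c.size]
    if not chosen:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chosen)).astype(np.int64)


def _tile_in_island(tile_coord: pd.DataFrame, cfg: SimulationConfig) -> np.ndarray:
    """Does each tile overlap the deterministic island grid?"""
    offset = cfg.island_spacing // 2
    start = tile_coord["start"].to_numpy()
    rel = (start - offset) % cfg.island_spacing
    return (rel < cfg.island_length) | (rel > cfg.island_spacing - cfg.tile_size)


def _headroom_baseline(rng, cfg: SimulationConfig, lo: float, hi: float) -> float:
    """Draw a tile baseline from the configured beta restricted to [lo, hi],
    so a planted shift stays realizable; falls back to uniform if the beta
    rarely lands in the window."""
    draws = rng.beta(cfg.baseline_meth_alpha, cfg.baseline_meth_beta, size=256)
    ok = draws[(draws >= lo) & (draws <= hi)]
    if ok.size:
        return float(ok[0])
    return float(rng.uniform(lo, hi))


def simulate_methylome(config: SimulationConfig):
    """Generate per-sample CpG count tables, ground truth, and peak intervals.

    Returns ``(samples, truth, peaks)`` where ``samples`` maps sample id
    (F1..Fn, M1..Mn) to a CpG count frame in the internal schema, ``truth``
    is a :class:`SimulationTruth`, and ``peaks`` equals ``truth.peaks``.

    Planted tiles are whole grid-aligned tiles on autosomes; the designated
    hyper sex is shifted up by ``planted_effect`` points (clamped to [0, 100],
    with the realized difference recorded in the truth table). On designated
    sex chromosomes every female sample is shifted up by ``x_hyper_shift``
    points. With a fixed seed the output is byte-identical across runs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tile = cfg.tile_size

    chroms, positions = [], []
    for name, length in cfg.chromosomes:
        pos = _cpg_positions(rng, length, cfg)
        chroms.append(np.full(pos.size, name, dtype=object))
        positions.append(pos)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    n_cpg = pos_arr.size
    if n_cpg == 0:
        raise ValueError("no CpGs generated; increase chromosome lengths or densities")

    tile_key = pd.DataFrame({"chrom": chrom_arr, "start": (pos_arr // tile) * tile})
    tiles, tile_of_cpg = np.unique(
        tile_key["chrom"].astype(str) + ":" + tile_key["start"].astype(str),
        return_inverse=True,
    )
    # recover ordered tile coordinate table
    tile_coord = (
        tile_key.assign(idx=tile_of_cpg)
        .drop_duplicates("idx")
        .sort_values("idx")[["chrom", "start"]]
        .reset_index(drop=True)
    )
    n_tiles = len(tile_coord)
    is_sex_tile = tile_coord["chrom"].isin(cfg.sex_chromosomes).to_numpy()

    baseline = rng.beta(cfg.baseline_meth_alpha, cfg.baseline_meth_beta, size=n_tiles)
    mean_f = baseline.copy()
    mean_m = baseline.copy()

    # --- plant differential tiles on autosomes -----------------------------
    # Planting is restricted to tiles with enough CpG support to carry a
    # testable signal but outside the extreme-density tail that the upper
    # coverage-percentile filter is designed to remove; planted tiles are
    # biased toward the open sea per planted_open_sea_fraction, echoing the
    # observation that sex differences concentrate outside CpG islands.
    cpgs_per_tile = np.bincount(tile_of_cpg, minlength=n_tiles)
    eligible = (
        ~is_sex_tile
        & (cpgs_per_tile >= cfg.min_cpgs_planted)
        & (cpgs_per_tile <= cfg.max_cpgs_planted)
    )
    in_island = _tile_in_island(tile_coord, cfg)
    open_cand = np.flatnonzero(eligible & ~in_island)
    island_cand = np.flatnonzero(eligible & in_island)
    if cfg.n_planted_dmts > len(open_cand) + len(island_cand):
        raise ValueError(
            f"cannot plant {cfg.n_planted_dmts} DMTs: only "
            f"{len(open_cand) + len(island_cand)} autosomal tiles carry "
            f"{cfg.min_cpgs_planted}-{cfg.max_cpgs_planted} CpGs "
            f"(short by {cfg.n_planted_dmts - len(open_cand) - len(island_cand)})"
        )
    n_open = min(int(round(cfg.planted_open_sea_fraction * cfg.n_planted_dmts)), len(open_cand))
    n_isl = min(cfg.n_planted_dmts - n_open, len(island_cand))
    n_open = cfg.n_planted_dmts - n_isl  # top up if one stratum ran short
    planted_idx = np.concatenate(
        [
            rng.choice(open_cand, size=n_open, replace=False),
            rng.choice(island_cand, size=n_isl, replace=False),
        ]
    ).astype(np.int64)
    rng.shuffle(planted_idx)
    n_female_hyper = int(round(cfg.female_hyper_fraction * cfg.n_planted_dmts))
    directions = np.array(
        [FEMALE_HYPER] * n_female_hyper + [MALE_HYPER] * (cfg.n_planted_dmts - n_female_hyper),
        dtype=object,
    )
    rng.shuffle(directions)
    effect = cfg.planted_effect / 100.0
    lo, hi = 0.02, 0.98 - effect
    truth_rows = []
    for idx, direction in zip(planted_idx, directions):
        if hi > lo:
            base = _headroom_baseline(rng, cfg, lo, hi)
        else:  # effect too large for headroom: keep the draw, clamp below
            base = baseline[idx]
        up = min(base + effect, 1.0)
        if direction == FEMALE_HYPER:
            mean_f[idx], mean_m[idx] = up, base
        else:
            mean_f[idx], mean_m[idx] = base, up
        realized = 100.0 * (mean_f[idx] - mean_m[idx])
        truth_rows.append(
            (
                tile_coord.at[idx, "chrom"],
                int(tile_coord.at[idx, "start"]),
                int(tile_coord.at[idx, "start"]) + tile,
                realized,
                direction,
            )
        )
    truth_table = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "true_difference", "direction"]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # --- female hypermethylation on sex chromosomes ------------------------
    if cfg.sex_chromosomes:
        mean_f[is_sex_tile] = np.minimum(mean_f[is_sex_tile] + cfg.x_hyper_shift / 100.0, 1.0)

    # --- per-CpG proportions and counts ------------------------------------
    jitter = rng.normal(0.0, cfg.within_tile_sd, size=n_cpg) if cfg.within_tile_sd > 0 else 0.0
    p_f = np.clip(mean_f[tile_of_cpg] + jitter, 0.0, 1.0)
    p_m = np.clip(mean_m[tile_of_cpg] + jitter, 0.0, 1.0)

    nb_n = cfg.coverage_dispersion
    nb_p = nb_n / (nb_n + cfg.coverage_mean)
    samples = {}
    for sex, props in (("F", p_f), ("M", p_m)):
        for i in range(cfg.n_per_group):
            cov = rng.negative_binomial(nb_n, nb_p, size=n_cpg)
            meth = rng.binomial(cov, props)
            samples[f"{sex}{i + 1}"] = pd.DataFrame(
                {
                    "chrom": chrom_arr,
                    "pos": pos_arr,
                    "strand": ".",
                    "n_meth": meth,
                    "n_unmeth": cov - meth,
                }
            )[CPG_COLUMNS]

    # --- peak intervals with planted DMT overlap ---------------------------
    n_in_dmt = int(round(cfg.peak_dmt_enrichment * min(cfg.n_planted_dmts, cfg.n_peak_intervals)))
    peak_rows = []
    chrom_len = dict(cfg.chromosomes)
    covered = rng.choice(len(truth_table), size=n_in_dmt, replace=False) if n_in_dmt else []
    pad = max((cfg.peak_length - tile) // 2, 0)
    for k, row_i in enumerate(covered):
        row = truth_table.iloc[int(row_i)]
        start = max(int(row["start"]) - pad, 0)
        end = min(int(row["end"]) + pad, chrom_len[row["chrom"]])
        peak_rows.append((row["chrom"], start, end, f"peak_dmt{k + 1}", 0.0))
    auto_names = [n for n, _ in cfg.chromosomes if n not in cfg.sex_chromosomes]
    for k in range(cfg.n_peak_intervals - n_in_dmt):
        name = auto_names[rng.integers(len(auto_names))]
        start = int(rng.integers(0, max(chrom_len[name] - cfg.peak_length, 1)))
        peak_rows.append((name, start, start + cfg.peak_length, f"peak_bg{k + 1}", 0.0))
    peaks = (
        pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name", "score"])
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )

    truth = SimulationTruth(table=truth_table, peaks=peaks, seed=cfg.seed, config=cfg)
    return samples, truth, peaks


def group_labels(samples) -> dict:
    """Sample id -> "female"/"male" from the F*/M* naming convention."""
    return {s: ("female" if s.startswith("F") else "male") for s in samples}


def write_truth_bed(truth: SimulationTruth, path) -> None:
    """Write planted tiles as BED6: name = direction, score = |true diff|."""
    if truth is None or truth.table is None:
        raise ValueError("truth is empty; nothing to write")
    with open(path, "w") as fh:
        for row in truth.table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.direction}\t"
                f"{abs(row.true_difference):g}\t.\n"
            )
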