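import numpy as np
import pandas as pd
import pytest

from tilemeth import (
    call_dmts,
    filter_by_coverage,
    group_labels,
    simulate_methylome,
    tile_counts,
)
from tilemeth.simulate import SimulationConfig

SMALL_GENOME = (("chr1", 600_000), ("chr2", 400_000))


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast synthetic methylome (3 vs 3, two short chromosomes)."""
    cfg = SimulationConfig(
        n_per_group=3,
        chromosomes=SMALL_GENOME,
        n_planted_dmts=20,
        n_peak_intervals=40,
        seed=11,
    )
    return simulate_methylome(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    samples, _, _ = small_sim
    return tile_counts(samples, group_labels(samples))


@pytest.fixture(scope="session")
def power_run():
    """Default study conditions: 6v6, 100 planted tiles at +40 points, 30x."""
    cfg = SimulationConfig(seed=101)
    samples, truth, peaks = simulate_methylome(cfg)
    tm = filter_by_coverage(tile_counts(samples, group_labels(samples)))
    calls, stats = call_dmts(tm)
    return {"truth": truth, "peaks": peaks, "tiles": tm, "calls": calls, "stats": stats}


def tile_set(frame: pd.DataFrame) -> set:
    return {
        (c, int(s), int(e))
        for c, s, e in zip(frame["chrom"], frame["start"], frame["end"])
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
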