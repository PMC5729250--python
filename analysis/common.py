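"""Shared plumbing for the numbered analysis drivers.

The drivers form one narrative: simulate an RRBS-like liver study (6 females
vs 6 males), call sex-differential tiles, summarise sample structure,
directional bias and annotation, test enhancer-peak enrichment, and compare
against a second simulated "tissue". Everything heavy lives in the tilemeth
package; these scripts only wire stages together and write result tables.

Large intermediates (per-sample coverage files, full per-tile statistics) go
under scratch/; small summary tables go under results/.
"""

from pathlib import Path

from tilemeth import (
    call_dmts,
    filter_by_coverage,
    group_labels,
    simulate_methylome,
    tile_counts,
)
from tilemeth.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 1

# The simulated study: six replicates per sex at ~30x, 100 planted
# sex-differential tiles at 40 points with an 80% female-hyper bias, and
# enhancer-like peaks placed over 80% of the planted tiles.
def study_config(seed: int = STUDY_SEED, **overrides) -> SimulationConfig:
    params = dict(seed=seed)
    params.update(overrides)
    return SimulationConfig(**params)


def simulate_study(seed: int = STUDY_SEED, **overrides):
    cfg = study_config(seed, **overrides)
    samples, truth, peaks = simulate_methylome(cfg)
    return cfg, samples, truth, peaks


def tile_and_call(samples):
    """Tile at 100 bp, apply the >10x / 99.8th-percentile filters, test."""
    tm = filter_by_coverage(tile_counts(samples, group_labels(samples)))
    calls, stats = call_dmts(tm)
    return tm, calls, stats


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
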