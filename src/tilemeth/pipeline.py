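"""Configuration-driven orchestration of the full analysis.

One declarative :class:`RunConfig` drives simulate-or-ingest → tile → filter
→ test → call → structure → annotate → enrich. Defaults are the analysis
parameters used throughout: 100-bp tiles, >10× coverage in every sample,
below the per-sample 99.8th coverage percentile, |Δmeth| ≥ 25 points,
q ≤ 0.01, and 10,000 permutation iterations. Given a seed, a run is fully
deterministic, and every number in the summary is recomputable from the
emitted stage tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import annotate, diffmeth, io_formats, simulate, structure, tiling


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Declarative parameters of one analysis run.

    Either ``simulation`` is set (synthetic mode) or ``samples`` maps sample
    id -> (path, dialect) with ``groups`` mapping sample id -> group label.
    """

    simulation: simulate.SimulationConfig | None = None
    samples: dict = field(default_factory=dict)  # sample -> (path, dialect)
    groups: dict = field(default_factory=dict)  # sample -> group label
    tile_size: int = 100
    min_coverage: int = 10
    max_percentile: float = 99.8
    diff_threshold: float = 25.0
    q_threshold: float = 0.01
    test_method: str = "logistic"
    group_order: tuple = ("female", "male")
    exclude_sex_chromosomes: bool = True
    sex_chromosome_names: tuple = ("chrX", "chrY")
    annotation_beds: dict = field(default_factory=dict)  # label -> BED path
    peak_beds: dict = field(default_factory=dict)  # mark name -> BED path
    n_iter: int = 10_000
    seed: int = 0

    def validate(self):
        if self.simulation is None and not self.samples:
            raise ValueError("config needs either a simulation block or a sample manifest")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if not 0 < self.diff_threshold <= 100:
            raise ValueError("diff_threshold must be in (0, 100]")
        if self.test_method not in diffmeth.TEST_METHODS:
            raise ValueError(f"unknown test method {self.test_method!r}")
        return self


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("ingest")
def _load_samples(config: RunConfig):
    if config.simulation is not None:
        sim_cfg = config.simulation
        samples, truth, peaks = simulate.simulate_methylome(sim_cfg)
        groups = simulate.group_labels(samples)
        return samples, groups, truth, peaks
    sites = {
        sid: io_formats.read_coverage_file(path, dialect)
        for sid, (path, dialect) in config.samples.items()
    }
    return sites, dict(config.groups), None, None


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Run the full analysis; returns the result bundle and optionally writes
    per-stage tables plus a machine-readable ``summary.json`` to ``outdir``.

    Bundle keys: tiles (filtered TileMatrix), stats (per-tile statistics),
    calls (DMT table), clustering, pca, bias, annotation (if configured),
    enrichment (per peak set, if configured), truth (synthetic mode), and
    summary (the JSON-serialisable report).
    """
    config.validate()
    samples, groups, truth, sim_peaks = _load_samples(config)

    tm = tiling.tile_counts(samples, groups, tile_size=config.tile_size)
    tm = tiling.filter_by_coverage(
        tm, min_coverage=config.min_coverage, max_percentile=config.max_percentile
    )
    n_retained_with_sex = tm.n_tiles
    if config.exclude_sex_chromosomes:
        tm = tiling.drop_chromosomes(tm, config.sex_chromosome_names)
        if tm.n_tiles == 0:
            raise PipelineError("stage 'filter' failed: no tiles left after sex-chromosome drop")

    calls, stats = diffmeth.call_dmts(
        tm,
        diff_threshold=config.diff_threshold,
        q_threshold=config.q_threshold,
        method=config.test_method,
        group_order=config.group_order,
    )

    pm = structure.percent_matrix(tm)
    clustering = structure.cluster_samples(pm)
    n_comp = min(3, tm.n_samples - 1)
    pca = structure.pca_samples(pm, n_components=n_comp)

    bias = annotate.direction_bias(calls) if len(calls) else None

    annotation = None
    if config.annotation_beds:
        feats = {label: io_formats.read_bed(p) for label, p in config.annotation_beds.items()}
        scheme = annotate.AnnotationScheme(features=feats)
        labels_all, frac_all = annotate.annotate_tiles(tm.tiles, scheme)
        frac_dmt = None
        if len(calls):
            _, frac_dmt = annotate.annotate_tiles(calls[["chrom", "start", "end"]], scheme)
        annotation = {"universe_fractions": frac_all, "dmt_fractions": frac_dmt,
                      "universe_labels": labels_all}

    enrichment = {}
    peak_sets = {name: io_formats.read_bed(p) for name, p in config.peak_beds.items()}
    if sim_peaks is not None and not peak_sets:
        peak_sets = {"planted_peaks": sim_peaks}
    if len(calls):
        for name, peaks in peak_sets.items():
            enrichment[name] = annotate.permutation_enrichment(
                calls[["chrom", "start", "end"]],
                tm.tiles,
                peaks,
                n_iter=config.n_iter,
                seed=config.seed,
            )

    summary = {
        "parameters": {
            "tile_size": config.tile_size,
            "min_coverage": config.min_coverage,
            "max_percentile": config.max_percentile,
            "diff_threshold": config.diff_threshold,
            "q_threshold": config.q_threshold,
            "test_method": config.test_method,
            "exclude_sex_chromosomes": config.exclude_sex_chromosomes,
            "n_iter": config.n_iter,
            "seed": config.seed,
        },
        "percentile_cuts": tm.provenance["filters"][0]["percentile_cuts"],
        "n_tiles_retained": int(tm.n_tiles),
        "n_tiles_retained_with_sex_chromosomes": int(n_retained_with_sex),
        "n_dmts": int(len(calls)),
        "fraction_female_hyper": (
            float(bias.loc[bias["chrom"] == "overall", "fraction_female_hyper"].iloc[0])
            if bias is not None
            else None
        ),
        "enrichment": {name: res.summary() for name, res in enrichment.items()},
        "leaf_order": clustering.leaf_order,
        "pca_explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
    }

    bundle = {
        "tiles": tm,
        "stats": stats,
        "calls": calls,
        "clustering": clustering,
        "pca": pca,
        "bias": bias,
        "annotation": annotation,
        "enrichment": enrichment,
        "truth": truth,
        "summary": summary,
    }
    if outdir is not None:
        _write_bundle(bundle, config, Path(outdir))
    return bundle


@_stage("write")
def _write_bundle(bundle, config: RunConfig, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["tiles"].to_tsv(outdir / "tile_matrix.tsv")
    bundle["stats"].to_csv(outdir / "tile_statistics.tsv", sep="\t", index=False)
    io_formats.write_dmt_table(bundle["calls"], outdir / "dmt_calls.tsv")
    if bundle["bias"] is not None:
        bundle["bias"].to_csv(outdir / "direction_bias.tsv", sep="\t", index=False)
    bundle["pca"].scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    (outdir / "dendrogram.nwk").write_text(bundle["clustering"].to_newick() + "\n")
    if bundle["truth"] is not None:
        simulate.write_truth_bed(bundle["truth"], outdir / "planted_truth.bed")
        io_formats.write_bed(bundle["truth"].peaks, outdir / "planted_peaks.bed")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2, default=_jsonable)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    return str(obj)


def compare_datasets(bundle_a: dict, bundle_b: dict, names=("A", "B")) -> dict:
    """Cross-dataset comparison on a shared tile grid.

    Reports the intersection of the two retained-tile universes, the tiles
    unique to either universe (so overlap denominators are explicit), and the
    Venn counts of the two DMT sets restricted to tile identity.
    """
    tm_a, tm_b = bundle_a["tiles"], bundle_b["tiles"]
    if tm_a.tile_size != tm_b.tile_size:
        raise ValueError(
            f"tile grids differ: {tm_a.tile_size} vs {tm_b.tile_size} bp"
        )
    uni_a, uni_b = set(tm_a.tile_ids()), set(tm_b.tile_ids())
    shared = uni_a & uni_b
    calls_a = {tuple(t) for t in bundle_a["calls"][["chrom", "start", "end"]].itertuples(index=False)}
    calls_b = {tuple(t) for t in bundle_b["calls"][["chrom", "start", "end"]].itertuples(index=False)}
    venn = annotate.overlap_dmt_sets({names[0]: calls_a, names[1]: calls_b}) if (
        calls_a or calls_b
    ) else {}
    report = {
        "universe_sizes": {names[0]: len(uni_a), names[1]: len(uni_b)},
        "universe_intersection": len(shared),
        "universe_unique": {
            names[0]: len(uni_a - uni_b),
            names[1]: len(uni_b - uni_a),
        },
        "dmt_counts": {names[0]: len(calls_a), names[1]: len(calls_b)},
        "dmt_venn": venn,
        "warning": None if shared else "tile universes are disjoint",
    }
    return report
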