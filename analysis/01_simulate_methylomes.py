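"""Generate the synthetic RRBS study: 12 Bismark-style coverage files
(6 females, 6 males), the planted ground truth, and enhancer-like peaks.

Coverage files land under scratch/simdata/ (they are inputs for the later
stages); the truth and peak BEDs, which are small, go to results/.
"""

from common import RESULTS, SCRATCH, ensure_dirs, simulate_study

from tilemeth import write_bed, write_coverage_file, write_truth_bed


def main():
    ensure_dirs()
    simdir = SCRATCH / "simdata"
    simdir.mkdir(exist_ok=True)
    cfg, samples, truth, peaks = simulate_study()
    for sid, sites in samples.items():
        write_coverage_file(sites, simdir / f"{sid}.cov")
    write_truth_bed(truth, RESULTS / "planted_truth.bed")
    write_bed(peaks, RESULTS / "planted_peaks.bed")
    n_cpg = len(next(iter(samples.values())))
    print(f"simulated {len(samples)} samples ({cfg.n_per_group} per sex), {n_cpg} CpGs each")
    print(f"planted {len(truth.table)} differential tiles at {cfg.planted_effect:+.0f} points "
          f"({(truth.table.direction == 'female-hyper').mean():.0%} female-hyper)")
    print(f"wrote coverage files to {simdir}")
    print(f"wrote {RESULTS/'planted_truth.bed'} and {RESULTS/'planted_peaks.bed'}")


if __name__ == "__main__":
    main()
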