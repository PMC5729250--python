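"""Compare the study against a second simulated "tissue".

Two tissues of the same individuals share CpG architecture only by chance
here (independent seeds), so this driver demonstrates the shared-universe
bookkeeping: intersection of retained-tile universes, tiles unique to each,
and the Venn partition of the two DMT sets by exact tile identity.
"""

import json

from common import RESULTS, ensure_dirs, study_config

from tilemeth import RunConfig, compare_datasets, run_pipeline


def main():
    ensure_dirs()
    liver = run_pipeline(RunConfig(simulation=study_config(), n_iter=1000, seed=1))
    # second tissue: same design, fewer sex differences, its own seed
    heart = run_pipeline(
        RunConfig(
            simulation=study_config(seed=2, n_planted_dmts=30, female_hyper_fraction=0.5),
            n_iter=1000,
            seed=2,
        )
    )
    rep = compare_datasets(liver, heart, names=("liver", "heart"))
    rep["dmt_venn"] = {"+".join(k): v for k, v in rep["dmt_venn"].items()}
    with open(RESULTS / "cross_tissue_overlap.json", "w") as fh:
        json.dump(rep, fh, indent=2)
    print(f"universe sizes: {rep['universe_sizes']}, shared {rep['universe_intersection']}")
    print(f"DMT counts: {rep['dmt_counts']}")
    print(f"DMT Venn regions: {rep['dmt_venn']}")
    print(f"wrote {RESULTS/'cross_tissue_overlap.json'}")


if __name__ == "__main__":
    main()
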