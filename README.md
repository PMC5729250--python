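# tilemeth

Tile-based analysis of sexually dimorphic DNA methylation from reduced
representation bisulphite sequencing (RRBS) count data.

Male and female mammals differ in cytosine methylation not only on the sex
chromosomes but at autosomal loci, with a characteristic bias towards
hypermethylation in females. Detecting those differences from RRBS requires
pooling the statistical evidence of neighbouring CpGs into fixed genomic
windows, filtering on read depth, testing each window between the sexes, and
then asking where the differential windows fall — in CpG islands or the open
sea, on which chromosomes, in which direction, and whether they pile up in
enhancer-like regions more than chance allows. `tilemeth` implements that
whole chain for anyone with per-CpG methylated/unmethylated count tables
(Bismark coverage files or cytosine reports), plus a synthetic-data generator
that emulates the RRBS study design so every stage can be exercised and
validated without any sequencing data.

## The method

Per-CpG counts from each sample are pooled into grid-aligned 100-bp tiles
(a CpG at position *p* belongs to tile ⌊*p*/100⌋). A tile enters the analysis
only if its read total exceeds 10× in **every** sample and does not exceed
that sample's 99.8th coverage percentile (a guard against PCR pileups). For
each retained tile with female pooled counts (m_F, t_F) and male pooled
counts (m_M, t_M), the group effect is tested by binomial logistic
regression of methylated counts on sex across replicates; with sex as the
only covariate the likelihood-ratio statistic has the closed form

    G = 2 [ ℓ(m_F, t_F, p̂_F) + ℓ(m_M, t_M, p̂_M) − ℓ(m_F+m_M, t_F+t_M, p̂_0) ],

where ℓ is the binomial log-likelihood and p̂ the pooled proportions, with
G ~ χ²(1) under the null. A pooled two-sided Fisher exact test is available
for single-replicate designs and as a cross-check. P-values are converted to
q-values by Benjamini–Hochberg step-up, and a tile is called a
**differentially methylated tile (DMT)** when

    |Δ| = |100·(p̂_F − p̂_M)| ≥ 25 percentage points  and  q ≤ 0.01.

Downstream summaries: hierarchical clustering of samples (distance
1 − Pearson r, Ward linkage) and PCA of the percent-methylation matrix,
per-chromosome fractions of female-hypermethylated DMTs, exclusive
island/shore/open-sea and genic annotation, Venn overlap of DMT sets across
datasets on a shared tile grid, and a permutation test of peak overlap: the
observed number of DMTs hitting a peak is compared with the overlap of
equally sized random tile sets drawn from the retained-tile universe, with
empirical p = (1 + #{null ≥ observed}) / (n_iter + 1).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(six females vs six males, ~30× depth, 100 planted sex-differential tiles of
40 percentage points, 80% hypermethylated in females). After
`python analysis/01_simulate_methylomes.py`:

```
$ python analysis/02_call_dmts.py
retained 14719 tiles after coverage filtering
called 99 DMTs (|diff| >= 25 points, q <= 0.01)
recovered 99/100 planted tiles, 0 spurious calls
```

So 14,719 of the tiled windows survive the depth filters, and the caller
finds 99 DMTs — 99 of the 100 planted differences, with no false positives.
Structure and bias follow the planted design:

```
$ python analysis/03_sample_structure.py
leaf order: F6 F5 F3 F4 F1 F2 M3 M5 M1 M2 M4 M6
top split separates the sexes exactly: True
explained variance (PC1-3): 13.4%, 9.1%, 8.9%

$ python analysis/04_direction_bias_annotation.py
99 DMTs, 80.8% hypermethylated in females
...

$ python analysis/05_peak_enrichment.py
79/99 DMTs overlap a peak; null mean 2.3 (sd 1.5) of 99
observed overlap fraction 79.8%
enrichment p < 1e-4 (empirical floor at 10000 iterations)
```

The dendrogram's top split recovers the sexes, 80.8% of DMTs are
female-hypermethylated (the planted fraction is 80%), and the planted enhancer-peak
enrichment drives the permutation p to its reporting floor of 10⁻⁴.
`analysis/06_cross_tissue_overlap.py` compares two simulated "tissues" and
reports the shared tile universe and the DMT Venn partition.

Programmatic use goes through `tilemeth.RunConfig` / `run_pipeline`, or the
individual functions (`tile_counts`, `filter_by_coverage`, `call_dmts`,
`cluster_samples`, `permutation_enrichment`, ...).

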