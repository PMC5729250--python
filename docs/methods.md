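# Methods

## Analysis model

The unit of analysis is a grid-aligned 100-bp genomic tile. Per-CpG
methylated/unmethylated read counts are summed over the CpGs of a tile,
separately per sample, after destranding (a minus-strand cytosine at
position *p* is pooled with its plus-strand partner at *p*−1; coverage-file
inputs carry no strand and are taken as already destranded). Tiles are
windows with step equal to width, never sliding.

Two coverage filters precede testing. A tile must exceed `min_coverage`
(default 10, strictly greater) reads in **every** sample, and must not
exceed the `max_percentile` (default 99.8) percentile of tile coverages in
**any** sample. The percentile cutoff is computed per sample over that
sample's covered tiles, with linear interpolation between order statistics;
a pooled-across-samples variant is available by flag. Ties at the cutoff are
retained, so a degenerate all-equal coverage distribution loses nothing —
this matches the behaviour of methylKit's coverage filter, whose upper cut
exists to remove PCR-duplicate pileups, not typical tiles. Realized cutoffs
are data-dependent and are recorded in the matrix provenance and the run
summary.

The two-group test is binomial logistic regression of methylated counts on
the group label across replicates, assessed by a likelihood-ratio test
against the intercept-only model. Because the group indicator is the only
covariate, the maximum-likelihood fit is analytic — each group's fitted
proportion is its pooled count proportion — so the statistic is computed in
closed form and vectorised over all tiles; the equivalence to a
per-replicate GLM fit is asserted in the test suite against statsmodels. No
overdispersion correction is applied (the default of the logistic approach
this follows); this is a known simplification, and on real data with strong
biological replicate variance it makes p-values anticonservative. The
pooled Fisher exact test is provided for n=1 groups and as a cross-check.

The methylation difference is the pooled-proportion difference in
percentage points, oriented female − male, so positive differences mean
female hypermethylation. Multiple testing uses Benjamini–Hochberg step-up
q-values (deterministic, in contrast to resampling-based alternatives, so
absolute call counts on real data may differ slightly from pipelines using
SLIM). Calls require |Δ| ≥ 25 points and q ≤ 0.01; the q comparison is
inclusive, with a strict-mode flag.

Sample structure uses distance 1 − Pearson correlation between sample
columns of the percent matrix and Ward minimum-variance linkage. Ward is
applied to the correlation distance directly, the convention of methylKit's
`clusterSamples`, although Ward's derivation assumes squared Euclidean
distances; the dendrogram should be read as a grouping heuristic, not a
metric tree. PCA is run on tile-centred, unscaled percent values; component
signs are fixed by making the largest-magnitude loading positive.

The permutation enrichment test counts query tiles overlapping ≥1 peak by
≥1 bp, then draws |query| tiles uniformly without replacement from the
retained-tile universe per iteration (literal index permutation, so the
draw generalises to weighted variants). The empirical p-value is
(1 + #{null ≥ observed}) / (n_iter + 1): it is never 0, and at the default
10,000 iterations its floor is just under 10⁻⁴, which is the natural
"p < 1×10⁻⁴" reporting convention. The depletion-side p is computed
analogously on the lower tail.

## Synthetic methylomes

The generator emulates the statistical structure of an RRBS sex-comparison
study, not its sequencing chemistry. Defaults, chosen once as the study
conditions:

| parameter | default | meaning |
|---|---|---|
| n_per_group | 6 | replicates per sex (isogenic) |
| chromosomes | 3 autosomes, 9 Mb total | desk-scale genome |
| coverage_mean / dispersion | 30 / 5 | negative-binomial depth per CpG per sample |
| baseline_meth_alpha, beta | 2, 2 | beta prior of per-tile baseline methylation |
| within_tile_sd | 0.02 | per-CpG jitter around the tile baseline (shared across samples) |
| n_planted_dmts / planted_effect | 100 / 40 points | true sex-differential tiles |
| female_hyper_fraction | 0.8 | planted direction bias |
| planted_open_sea_fraction | 0.8 | planted tiles placed outside island-like regions |
| x_hyper_shift | 30 points | female shift on designated sex chromosomes |
| peak_dmt_enrichment | 0.8 | fraction of planted tiles covered by peak intervals |

CpG positions are a Poisson process, dense (20/kb) inside a deterministic
grid of 1-kb island-like runs every 20 kb and sparse (2/kb) outside, plus
fragment-like open-sea clusters (0.3/kb, ~3 CpGs within 80 bp) mirroring the
capture unit of reduced-representation libraries — without them no open-sea
tile would carry enough CpGs to analyse. Each tile draws a baseline
methylation level from Beta(2, 2) shared by all samples; per-CpG proportions
add a small normal jitter (also shared across samples, preserving replicate
correlation); read depth is negative-binomial per CpG per sample; methylated
counts are binomial. The marginal per-CpG counts are therefore
beta-binomial around the tile baseline.

Planted tiles are whole grid tiles on autosomes carrying 3–4 CpGs: enough
support to be testable, but outside the extreme CpG-density tail that the
upper coverage-percentile filter removes — planting truth the study's own
filters are designed to discard would conflate generator and filter
behaviour. Their baselines are drawn from the same beta restricted so that
baseline + effect stays inside [0.02, 0.98]; when a configured effect is too
large for any headroom the shift is clamped, and the truth table always
records the realized (post-clamp) signed difference, so recovery is judged
against achievable effects. The hyper sex is shifted up by the effect;
directions are assigned to hit the configured female-hyper fraction exactly.
Designated sex chromosomes give every female sample a constant +30-point
shift (clamped), used to exercise the sex-chromosome exclusion switch.
Peak intervals of 600 bp are placed over a configured fraction of planted
tiles, the remainder uniformly on autosomes.

What the generator does **not** emulate, hence what green tests do not show
about real data: the bimodal (near-0/near-1) baseline distribution of real
methylomes — a moderate Beta(2, 2) is used so the null testing surface is
informative rather than degenerate; biological replicate overdispersion
beyond the shared-baseline model; coverage correlation along fragments;
bisulphite conversion error; and any realistic genome annotation. Headline
counts from real studies (e.g. absolute DMT numbers per tissue) depend on
genome-scale data and vendor preprocessing and are out of desk-scale reach;
the pipeline's claims on real data rest on the correctness of each operation,
not on reproducing those totals.

## Numerical and design choices

- Internal coordinates are uniformly 0-based half-open; the two supported
  input dialects (Bismark coverage, 1-based inclusive; cytosine report,
  1-based) are converted exactly once at the I/O boundary, guarded by an
  explicit dialect tag. %methylation columns are never trusted; counts win.
- The binomial log-likelihood kernel uses `xlogy`, so boundary proportions
  (0 or 1) contribute exactly zero rather than NaN; tiny negative LRT
  statistics from round-off are clamped to 0.
- Tiles where a whole group has zero pooled reads are untestable: they stay
  in the per-tile table flagged `tested=False` with NaN statistics (keeping
  the enrichment universe explicit) and are excluded from q-value ranking.
- Dendrogram leaf order is scipy's deterministic order for a fixed input;
  sample columns are passed in manifest order, making runs reproducible.
- DMT tables are written with 17 significant digits so re-reading reproduces
  calls bit-exactly.
- Venn overlap across datasets is exact tile-identity membership on a shared
  grid; mixing tile sizes is an error rather than a silent interval join.
- Problem sizes in the test suite and acceptance script (9-Mb genomes,
  ~12–15k retained tiles, 1,000–10,000 permutation iterations, 200
  calibration repetitions) were chosen so each statistical check has the
  resolution it claims (e.g. ≥10,000 null tiles for Kolmogorov–Smirnov
  uniformity) while a full run stays in the minutes range on one CPU.

## Known limitations

- No overdispersion/beta-binomial test; no covariates or paired designs.
- The permutation null resamples tiles uniformly; it is not matched on GC,
  CpG density or coverage, so enrichment against annotations correlated
  with those covariates inherits their confounding.
- Annotation is any-overlap with a fixed precedence order; fractional
  overlap rules are deliberately not offered.
- The generator's island grid is periodic and deterministic — convenient
  for exact island/shore bookkeeping, unrealistic as genome architecture.
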