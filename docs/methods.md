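# Methods

## Scope and model

`acylscape` implements an integrative analysis of three active chromatin
marks — H3K9ac (histone H3 lysine-9 acetylation), Kbu (lysine
butyrylation), and Kcr (lysine crotonylation) — profiled by ChIP-seq in
two replicates per condition, together with RNA-seq expression under
control, starvation, and submergence conditions and a four-time-point
diurnal course. The analysis answers five questions per gene: is it
marked (per mark and in which of the eight combinations), how is the
total acylation signal apportioned among the three marks, does the
modification change between conditions, does expression change, and is
expression diurnally rhythmic; plus, at the gene-set level, whether mark
combinations are over-represented among responsive genes.

### Coordinate and quantification conventions

All internal coordinates are 0-based half-open; GFF3 input (1-based
inclusive) is converted once at the file boundary, and written back
exactly on output. Peak sets are merged (overlapping *and* bookended
intervals collapsed — adjacent peak fragments represent one enriched
region) and sorted, so every overlap query is a binary search on
disjoint intervals.

ChIP signal is quantified as **TPM = tags per kilobase of region per
million mapped tags**: `TPM(g) = C(g)·1e9 / (L(g)·N)` with `C` the tag
count apportioned to the region proportionally to overlap length
(fractional tags allowed — deterministic and unbiased relative to
midpoint assignment), `L` the region length, and `N` the library size.
This is a ChIP-enrichment density, unrelated to RNA-seq
transcripts-per-million. A conservation identity (summing per-bin TPM
recovers the binned tag total exactly) is enforced by test.

*Upstream regions are strand-aware.* "2 kb upstream" of a minus-strand
gene lies beyond its right coordinate; regions are clipped at chromosome
edges, and a fully clipped region is reported as missing rather than
divided by zero.

### Marked genes and combinations

A gene is **marked** when a peak overlaps its body or 2-kb upstream
window in *both* replicates (AND rule; replication is the filter). The
three boolean calls define eight mutually exclusive combination labels
that partition the gene universe; marginal totals and overlaps are
computed from the partition, so partition consistency is structural, not
tested-for. One peak may mark several genes (the rule is stated per
gene, not per peak). Peak genomic context is assigned with priority
genic > promoter (upstream window) > intergenic, carrying the feature
class of the maximally overlapped gene (ties resolved to coding).

### Acylation proportions

For each gene, the **acylation proportion** of mark *m* is its
replicate-averaged gene-body TPM divided by the summed body TPM of the
three marks. The triple lives on the 2-simplex, so between-condition
deltas are zero-sum per gene: a gene can only trade acetylation share
against acylation share. Genes with zero total acylation are flagged
missing (not 0/0). Proportions use body-only TPM; the body+upstream
region is used only for the marked-gene rule.

### Differential rules

* **Modification**: per replicate pair, fold change
  `(TPM_t + ε)/(TPM_c + ε)` with ε = 1 TPM (bounds fold changes on empty
  genes); called up when FC > 1.5 in both replicates, down when
  FC < 1/1.5 in both. Replicates are paired by index, matching the
  two-replicate design.
* **Expression**: per-gene t-test on log2(count+1), BH-adjusted across
  genes; called at FDR < 0.05 **and** fold change > 4. The default test
  is an empirical-Bayes *moderated* t: the pooled log-scale residual
  variance is shrunk toward a prior fitted as a scaled F distribution
  (moment estimation of the prior df via the trigamma inverse, the
  standard small-sample RNA-seq treatment). A plain per-gene Welch test
  is available (`method="welch"`) but is severely underpowered at n = 2–3
  replicates, where ~4 residual df cannot yield p-values small enough to
  survive the BH step-up even for true 8-fold changes; precomputed
  per-gene p-values from an external DE engine are also accepted.
* **Diurnal**: the expression rule at FC > 2 applied to each of the six
  unordered pairs among the four time points, with BH adjustment within
  each comparison (mirroring per-comparison DE analysis); a gene is
  diurnal when at least 3 ("more than two") comparisons are significant.
  This reading is strict; `min_comparisons` is configurable.

### Enrichment

Combination-category enrichment within a gene subset uses the one-sided
hypergeometric tail (exact for subset-vs-background category counts),
flagged at p < 0.01; a Pearson chi-squared route is available for parity
with GO-style analysis. Generic gene-set enrichment uses Pearson's
chi-squared on the 2×2 membership table (1 df, no continuity
correction — the named test, uncorrected) with BH FDR across terms at
cutoff 0.05. Zero-margin tables report missing p-values, which propagate
through the FDR adjustment without shrinking other terms' ranks
incorrectly (missing entries are excluded from m).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with truth tables for recovery testing. Defaults define the study
conditions; they are not tuned per experiment.

| Parameter | Default | Meaning |
|---|---|---|
| `n_genes` / `n_chroms` | 20,000 / 12 | desk-scale genome, ~130 Mb |
| `gene_length_median`, `sigma` | 2 kb, 0.6 | lognormal gene lengths |
| `gene_spacing` | ≥ 4 kb | keeps TSS kernels of neighbours disjoint |
| `category_freqs` | published Venn counts / 56,384 | 8-way label frequencies |
| `te_fraction` | 0.3 | TE-related gene share |
| `depth` | 50 tags | expected tags per marked gene |
| `background_rate` | 0.5 tags/kb | Poisson background |
| `peak_detect_prob` | 0.95 | per-replicate peak emission for marked genes |
| `false_peak_rate` | 0.01 | per-replicate spurious peak at an unmarked locus |
| `replicate_dispersion` | 0.05 | NB dispersion of per-replicate tag totals |
| `intensity_sigma` | 0.8 (H3K9ac), 0.4 (Kbu/Kcr) | gene-level lognormal depth spread |
| `expr_intercept_log2` | 8 | baseline ≈ 256 counts/gene (a 5–20M-read library) |
| `n_expr_reps` | 3 | RNA-seq replicates |
| `n_deg`, `deg_log2fc` | 500, 3 | planted DEGs per treatment, 8-fold |
| `mod_coupling` | 0.5 (H3K9ac), 0 (Kbu/Kcr) | mark-TPM log2 shift per DEG log2FC |
| `n_diurnal`, `diurnal_amplitude` | 1000, 2 | sinusoidal genes, log2 peak-to-trough |

Design choices worth stating:

* **TSS-triangular kernel** over [TSS−500, TSS+1500], strand-oriented,
  apex mid-support. No quantitative spatial profile is prescribed by the
  study design being emulated; the kernel width is a free default and
  reproduces a 5′-shoulder metagene curve.
* **Gene-level mark intensity** is a lognormal multiplier (mean 1)
  shared across replicates and conditions — a gene's intrinsic
  enrichment — with per-replicate NB noise on top. H3K9ac gets a wider
  sigma than Kbu/Kcr so its acylation share spreads more, matching the
  observation that the acetylation proportion is the more dynamic one.
* **Expression coupling**: log2 mean = intercept + per-mark additive
  effects (1.5 for H3K9ac, 0.5 each for Kbu/Kcr) + 2.0 × H3K9ac
  proportion + N(0, 1) gene noise. Coupling to the *proportion*, not
  only presence, lets proportion-band analyses recover a planted trend.
* **Planted DEGs are drawn from genes carrying at least one mark**: the
  design requires their H3K9ac TPM to co-shift with expression, which
  needs a mark signal to shift, and stress-responsive genes are
  acylation-marked in this system. Their H3K9ac depth is multiplied by
  `2^(0.5·±3)` in the treated condition.
* **Detection independence**: peak emission is independent across
  replicates given the truth. Under the AND rule this fixes per-mark
  sensitivity at 0.95² ≈ 0.9025 and false marking at ≈ 0.01² = 1e-4,
  and caps expected 8-way label accuracy at
  Σ_k freq(k-mark labels)·0.9025^k ≈ 0.88 under the default label
  frequencies — a structural consequence worth knowing when reading
  recovery numbers.
* **TE status is drawn independently of the combination label**, keeping
  label marginals exact; real TE genes are depleted of active marks, so
  mark×TE correlations are *not* emulated.

What the generator does **not** emulate: read-level data (mappability,
GC bias, duplicates), peak-caller behaviour (peaks are emitted directly
from truth), correlated detection failures between replicates (weakly
enriched genes failing in both), input/control tracks, isoform
structure, and mark–mark spatial interactions beyond shared labels.
Passing recovery tests therefore demonstrates that the *decision rules*
behave as intended under the assumed noise laws, not that the pipeline
is robust to upstream artefacts of real sequencing data.

## Numerical choices

* bedGraph records are apportioned into fixed-width bins by overlap
  length; partially covered bins contribute fractionally (tags uniform
  within a record). Binned prefix sums make every interval query O(log).
* Metagene profiles: 2-kb flanks in fixed 50-bp bins, gene bodies
  length-normalised into 40 equal bins (a flat 50-bp grid cannot be
  averaged across unequal gene lengths); bins oriented 5′→3′; flank bins
  running off a chromosome end are dropped from the average, not zeroed.
* Correlation matrices are Pearson by default (Spearman by flag);
  zero-variance vectors yield missing entries, with the diagonal pinned
  to 1.
* BH adjustment excludes missing p-values from m and propagates them.
* Expression summaries use the transform log10(FPKM + 0.001) (zero maps
  to −3) and median/quartiles rather than means, matching box-style
  reporting of skewed expression distributions.
* Determinism: every stochastic draw flows through seeds spawned from a
  single config seed per stage, so identical configs reproduce outputs
  bit-for-bit; the pipeline report embeds the seed and a hash of the
  analytic configuration (output paths excluded).

## Problem sizes used in validation

The shipped validation suite runs the marked-gene recovery at the full
default scale (20,000 genes, peaks only), differential calibration on
100 simulations of 2,000 genes (3 replicates, dispersion 0.05), diurnal
recovery on a 2,000-gene course with 200 planted sinusoids, and
proportion/correlation recovery on a 4,000-gene two-condition study with
full coverage tracks. These sizes give binomial standard errors well
below the margins being asserted while keeping the whole suite in the
tens of seconds.

## Known limitations

* The moderated t on log2(count+1) is a pragmatic DE engine; it does not
  model NB mean–variance explicitly (no dispersion shrinkage across the
  mean range) and is not a substitute for a full count-model fit when
  library sizes are very unequal.
* The replicate-consistency rule for modification changes has no error
  control; its false-positive rate is set by the TPM noise level and the
  1.5-fold threshold (a few percent of genes at default noise), which
  matches how such rules behave on real data.
* Diurnal classification by pairwise contrasts is phase-sensitive: a
  sinusoid sampled at four points near the phase where two time points
  coincide yields borderline 2-fold contrasts, so sensitivity for
  amplitude-2 rhythms plateaus around 0.8–0.85 rather than 1.
* Enrichment assumes a fixed, complete universe; no GO DAG propagation.
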