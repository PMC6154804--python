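"""Synthetic multi-mark ChIP-seq + RNA-seq generator with ground truth.

The generator emulates the statistical structure of a three-mark histone
acylation study in a plant genome: ~20,000 genes on a handful of
chromosomes, three marks (H3K9ac, Kbu, Kcr) x two ChIP replicates x three
conditions (control, starvation, submergence), a diurnal RNA-seq course at
four time points, TSS-proximal enrichment of all three marks, expression
coupled to mark presence and to the H3K9ac share of total acylation, and
planted differentially expressed / diurnal genes whose H3K9ac signal
co-shifts with expression.

Every draw is routed through seeds derived from ``SimulationConfig.seed``,
so all outputs are reproducible bit-for-bit for a given config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic_io import (
    COMBINATION_LABELS,
    MARKS,
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    Interval,
    PeakSet,
)

CONDITIONS = ("control", "starvation", "submergence")
TREATMENTS = ("starvation", "submergence")
TIMEPOINTS = ("T0", "T6", "T12", "T18")

#: Mark-combination frequencies taken from the published Venn category
#: counts over 56,384 rice gene models (category N / 56,384).
DEFAULT_CATEGORY_FREQS: dict[str, float] = {
    "none": 28196 / 56384,
    "H3K9ac": 418 / 56384,
    "Kbu": 1234 / 56384,
    "Kcr": 784 / 56384,
    "H3K9ac+Kbu": 229 / 56384,
    "H3K9ac+Kcr": 217 / 56384,
    "Kbu+Kcr": 4795 / 56384,
    "H3K9ac+Kbu+Kcr": 20511 / 56384,
}

#: Kernel support around the TSS, strand oriented: 500 bp upstream to
#: 1500 bp downstream, apex mid-support.  Genes far closer than ~4 kb
#: apart would smear into each other; the annotation generator enforces
#: that spacing.
KERNEL_UP = 500
KERNEL_DOWN = 1500
KERNEL_SPAN = KERNEL_UP + KERNEL_DOWN


@dataclass
class SimulationConfig:
    """All knobs of the generator, with study-scale defaults."""

    n_genes: int = 20000
    n_chroms: int = 12
    gene_length_median: float = 2000.0
    gene_length_sigma: float = 0.6
    gene_spacing: int = 4000
    chrom_size: int | None = None  # fixed size; None = auto-fit
    te_fraction: float = 0.3
    category_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_FREQS)
    )
    # ChIP signal
    depth: float = 50.0  # expected tags per marked gene
    background_rate: float = 0.5  # tags per kb in unmarked regions
    peak_detect_prob: float = 0.95  # per replicate, per truly marked gene
    false_peak_rate: float = 0.01  # per replicate, per unmarked gene locus
    replicate_dispersion: float = 0.05  # NB dispersion of per-replicate tags
    bin_width: int = 50
    # gene-level mark intensity spread (lognormal sigma; mean fixed at 1);
    # H3K9ac wider than Kbu/Kcr so its acylation share varies more
    intensity_sigma: dict[str, float] = field(
        default_factory=lambda: {"H3K9ac": 0.8, "Kbu": 0.4, "Kcr": 0.4}
    )
    # expression model
    expr_intercept_log2: float = 8.0
    expr_gene_sigma: float = 1.0
    expr_dispersion: float = 0.05
    n_expr_reps: int = 3
    mark_effects: dict[str, float] = field(
        default_factory=lambda: {"H3K9ac": 1.5, "Kbu": 0.5, "Kcr": 0.5}
    )
    proportion_slope: float = 2.0  # log2 expression per unit H3K9ac proportion
    # planted effects
    n_deg: int = 500
    deg_log2fc: float = 3.0
    mod_coupling: dict[str, float] = field(
        default_factory=lambda: {"H3K9ac": 0.5, "Kbu": 0.0, "Kcr": 0.0}
    )
    n_diurnal: int = 1000
    diurnal_amplitude: float = 2.0  # log2 peak-to-trough
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        total = sum(self.category_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_freqs must sum to 1, got {total}")
        if set(self.category_freqs) != set(COMBINATION_LABELS):
            raise ValueError("category_freqs must cover all 8 combination labels")
        for name, p in (
            ("te_fraction", self.te_fraction),
            ("peak_detect_prob", self.peak_detect_prob),
            ("false_peak_rate", self.false_peak_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.replicate_dispersion <= 0 or self.expr_dispersion <= 0:
            raise ValueError("dispersions must be > 0")


def _rng(config: SimulationConfig, *tag: int) -> np.random.Generator:
    """Independent generator for one stage, derived from the config seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, *tag]))


@dataclass
class TruthTable:
    """Ground truth for recovery tests, one row per gene.

    Columns: ``label`` (combination category), ``marked_<mark>`` booleans,
    ``intensity_<mark>`` (gene-level depth multiplier, 0 when unmarked),
    ``p_<mark>`` (true acylation proportions; NaN when unmarked by all),
    ``deg_starvation``/``deg_submergence`` in {-1, 0, +1}, ``diurnal``
    flag and ``diurnal_phase``.
    """

    df: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.df["label"]

    def marked(self, mark: str) -> pd.Series:
        return self.df[f"marked_{mark}"]

    def deg_sign(self, condition: str) -> pd.Series:
        return self.df[f"deg_{condition}"]


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with >= ``gene_spacing`` bp gaps.

    Genes are dealt round-robin onto ``n_chroms`` synthetic chromosomes;
    lengths are lognormal around ``gene_length_median``; strands and
    TE-status are random.  Deterministic given the config seed.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    if n == 0:
        return GenomeAnnotation([], {})
    lengths = rng.lognormal(math.log(config.gene_length_median), config.gene_length_sigma, n)
    lengths = np.maximum(200, lengths.round().astype(np.int64))
    gaps = config.gene_spacing + rng.integers(0, 2000, n)
    strands = rng.choice(["+", "-"], n)
    te = np.zeros(n, dtype=bool)
    n_te = int(round(config.te_fraction * n))
    if n_te:
        te[rng.choice(n, n_te, replace=False)] = True
    chrom_of = np.arange(n) % config.n_chroms
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    width = len(str(max(n - 1, 1)))
    for c in range(config.n_chroms):
        idx = np.flatnonzero(chrom_of == c)
        if idx.size == 0:
            continue
        chrom = f"chr{c + 1}"
        pos = 0
        for i in idx:
            start = pos + int(gaps[i])
            end = start + int(lengths[i])
            genes.append(
                GeneModel(
                    f"g{i:0{width}d}",
                    Interval(chrom, start, end, str(strands[i])),
                    "te_related" if te[i] else "coding",
                )
            )
            pos = end
        size = pos + config.gene_spacing
        if config.chrom_size is not None:
            if size > config.chrom_size:
                raise ValueError(
                    f"genes do not fit on {chrom}: need {size} bases but "
                    f"chrom_size={config.chrom_size}; increase chrom_size or "
                    f"reduce n_genes/gene_spacing"
                )
            size = config.chrom_size
        chrom_sizes[chrom] = size
    genes.sort(key=lambda g: g.gene_id)
    return GenomeAnnotation(genes, chrom_sizes)


def generate_truth(config: SimulationConfig, annotation: GenomeAnnotation) -> TruthTable:
    """Draw combination labels, mark intensities, and planted effects."""
    rng = _rng(config, 2)
    gene_ids = annotation.gene_ids
    n = len(gene_ids)
    labels_all = list(config.category_freqs)
    probs = np.array([config.category_freqs[l] for l in labels_all])
    labels = rng.choice(labels_all, n, p=probs / probs.sum())
    df = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    df["label"] = labels
    for mark in MARKS:
        marked = np.array([mark in l.split("+") for l in labels])
        sigma = config.intensity_sigma[mark]
        intensity = rng.lognormal(-0.5 * sigma**2, sigma, n)  # E = 1
        df[f"marked_{mark}"] = marked
        df[f"intensity_{mark}"] = np.where(marked, intensity, 0.0)
    total = sum(df[f"intensity_{m}"] for m in MARKS)
    for mark in MARKS:
        df[f"p_{mark}"] = np.where(total > 0, df[f"intensity_{mark}"] / total, np.nan)
    any_marked = np.array([l != "none" for l in labels])
    for cond in TREATMENTS:
        sign = np.zeros(n, dtype=np.int64)
        candidates = np.flatnonzero(any_marked)
        n_deg = min(config.n_deg, candidates.size)
        if n_deg:
            chosen = rng.choice(candidates, n_deg, replace=False)
            s = np.where(np.arange(n_deg) % 2 == 0, 1, -1)
            sign[chosen] = rng.permutation(s)
        df[f"deg_{cond}"] = sign
    diurnal = np.zeros(n, dtype=bool)
    n_di = min(config.n_diurnal, n)
    if n_di:
        diurnal[rng.choice(n, n_di, replace=False)] = True
    df["diurnal"] = diurnal
    df["diurnal_phase"] = np.where(diurnal, rng.uniform(0, 2 * np.pi, n), 0.0)
    return TruthTable(df)


@dataclass
class ChipSample:
    """One mark x replicate ChIP sample under one condition."""

    track: CoverageTrack | None
    peaks: PeakSet


def _kernel_windows(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Strand-oriented TSS enrichment window per gene (unclipped)."""
    df = annotation.df
    plus = (df["strand"] == "+").to_numpy()
    tss = np.where(plus, df["start"].to_numpy(), df["end"].to_numpy())
    start = np.where(plus, tss - KERNEL_UP, tss - KERNEL_DOWN)
    return pd.DataFrame(
        {"gene_id": df["gene_id"], "chrom": df["chrom"], "start": start,
         "end": start + KERNEL_SPAN}
    )


def _depth_multiplier(
    config: SimulationConfig, truth: TruthTable, mark: str, condition: str
) -> np.ndarray:
    """Per-gene mark-depth fold relative to control for a condition."""
    n = len(truth.df)
    if condition == "control" or condition not in TREATMENTS:
        return np.ones(n)
    kappa = config.mod_coupling.get(mark, 0.0)
    sign = truth.deg_sign(condition).to_numpy()
    return np.power(2.0, kappa * config.deg_log2fc * sign)


def generate_chip(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: TruthTable,
    condition: str = "control",
    coverage: bool = True,
) -> dict[tuple[str, int], ChipSample]:
    """Generate coverage tracks and peak calls for every mark x replicate.

    Tag totals per truly marked gene are negative-binomial around
    ``depth x intensity`` (x a condition fold for planted DEGs) and are
    spread over a triangular TSS kernel; background is Poisson genome
    wide.  A peak spanning the kernel window is emitted per replicate
    with probability ``peak_detect_prob`` for marked genes and
    ``false_peak_rate`` for unmarked gene loci.  With ``coverage=False``
    only peaks are generated (same peak draws either way).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cond_i = CONDITIONS.index(condition)
    gdf = annotation.df
    windows = _kernel_windows(annotation)
    n = len(gdf)
    w = config.bin_width
    nk = KERNEL_SPAN // w
    ramp = np.minimum(np.arange(1, nk + 1), np.arange(nk, 0, -1)).astype(float)
    kernel = ramp / ramp.sum()
    r_nb = 1.0 / config.replicate_dispersion

    out: dict[tuple[str, int], ChipSample] = {}
    for mi, mark in enumerate(MARKS):
        marked = truth.marked(mark).to_numpy()
        mult = _depth_multiplier(config, truth, mark, condition)
        mean = config.depth * truth.df[f"intensity_{mark}"].to_numpy() * mult
        for rep in (1, 2):
            rng_tags = _rng(config, 3, cond_i, mi, rep, 0)
            rng_bg = _rng(config, 3, cond_i, mi, rep, 1)
            rng_peak = _rng(config, 3, cond_i, mi, rep, 2)
            sample_id = f"{condition}_{mark}_rep{rep}"

            # peaks (drawn from their own stream so skipping coverage
            # leaves them unchanged)
            u = rng_peak.random(n)
            detected = marked & (u < config.peak_detect_prob)
            false_hit = ~marked & (u < config.false_peak_rate)
            emit = detected | false_hit
            sizes = windows["chrom"].map(annotation.chrom_sizes).to_numpy()
            pk = windows.loc[emit, ["chrom", "start", "end"]].copy()
            pk["start"] = np.maximum(0, pk["start"])
            pk["end"] = np.minimum(sizes[emit], pk["end"])
            peaks = PeakSet(sample_id, mark, rep, pk)

            track = None
            if coverage:
                values: dict[str, np.ndarray] = {
                    chrom: np.zeros(-(-size // w), dtype=np.float64)
                    for chrom, size in annotation.chrom_sizes.items()
                }
                if n and config.depth > 0:
                    midx = np.flatnonzero(marked)
                    mu = np.maximum(mean[midx], 1e-12)
                    tags = rng_tags.negative_binomial(r_nb, r_nb / (r_nb + mu))
                    split = rng_tags.multinomial(tags, kernel)
                    start_bin = (windows["start"].to_numpy()[midx] // w).astype(np.int64)
                    for chrom, grp in gdf.iloc[midx].groupby("chrom", sort=False):
                        arr = values[chrom]
                        # grp.index holds integer positions into gdf (RangeIndex)
                        rows = np.searchsorted(midx, grp.index.to_numpy())
                        bins = start_bin[rows, None] + np.arange(nk)[None, :]
                        np.clip(bins, 0, arr.size - 1, out=bins)
                        np.add.at(arr, bins.ravel(), split[rows].ravel().astype(float))
                lam = config.background_rate * w / 1000.0
                for chrom in values:
                    values[chrom] += rng_bg.poisson(lam, values[chrom].size)
                total = float(sum(a.sum() for a in values.values()))
                track = CoverageTrack(
                    sample_id, mark, rep, w, max(total, 1.0), values
                )
            out[(mark, rep)] = ChipSample(track, peaks)
    return out


@dataclass
class ExpressionData:
    """Counts and FPKM matrices per condition plus a diurnal course."""

    counts: dict[str, pd.DataFrame]  # condition -> genes x replicates
    fpkm: dict[str, pd.DataFrame]
    timepoint_counts: dict[str, pd.DataFrame]  # time point -> genes x reps


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    mu = np.maximum(mean, 1e-12)
    return rng.negative_binomial(r, r / (r + mu)).astype(np.int64)


def _fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    lib = counts.sum(axis=0).astype(float)
    return counts.div(lib, axis=1).div(lengths.to_numpy(), axis=0) * 1e9


def generate_expression(
    config: SimulationConfig, truth: TruthTable, annotation: GenomeAnnotation
) -> ExpressionData:
    """Counts coupled to mark status and the H3K9ac acylation share.

    log2 mean = intercept + sum of per-mark effects + slope x p(H3K9ac)
    + gene noise; planted DEGs shift by ±deg_log2fc under their
    treatment; planted diurnal genes ride a sinusoid over the four time
    points with the configured log2 peak-to-trough amplitude.
    """
    rng = _rng(config, 4)
    tdf = truth.df
    n = len(tdf)
    lengths = annotation.gene_lengths().reindex(tdf.index)
    base = np.full(n, config.expr_intercept_log2)
    for mark in MARKS:
        base = base + config.mark_effects[mark] * tdf[f"marked_{mark}"].to_numpy()
    p_k9 = np.nan_to_num(tdf["p_H3K9ac"].to_numpy(), nan=0.0)
    base = base + config.proportion_slope * p_k9
    base = base + rng.normal(0.0, config.expr_gene_sigma, n)

    counts: dict[str, pd.DataFrame] = {}
    fpkm: dict[str, pd.DataFrame] = {}
    for cond in CONDITIONS:
        mu_log2 = base.copy()
        if cond in TREATMENTS:
            mu_log2 = mu_log2 + config.deg_log2fc * truth.deg_sign(cond).to_numpy()
        mu = np.power(2.0, mu_log2)
        cols = {}
        for rep in range(1, config.n_expr_reps + 1):
            cols[f"{cond}_r{rep}"] = _nb_counts(rng, mu, config.expr_dispersion)
        counts[cond] = pd.DataFrame(cols, index=tdf.index)
        fpkm[cond] = _fpkm(counts[cond], lengths)

    timepoint_counts: dict[str, pd.DataFrame] = {}
    phase = tdf["diurnal_phase"].to_numpy()
    amp = np.where(tdf["diurnal"].to_numpy(), config.diurnal_amplitude / 2.0, 0.0)
    for k, tp in enumerate(TIMEPOINTS):
        mu = np.power(2.0, base + amp * np.sin(2 * np.pi * k / len(TIMEPOINTS) + phase))
        cols = {}
        for rep in range(1, config.n_expr_reps + 1):
            cols[f"{tp}_r{rep}"] = _nb_counts(rng, mu, config.expr_dispersion)
        timepoint_counts[tp] = pd.DataFrame(cols, index=tdf.index)
    return ExpressionData(counts, fpkm, timepoint_counts)


def write_simulation(
    config: SimulationConfig,
    outdir,
    conditions: tuple[str, ...] = CONDITIONS,
    coverage: bool = True,
) -> None:
    """Materialise a simulated study as the flat files the readers accept.

    Writes ``genes.gff3``, ``truth.tsv``, per-sample ``<cond>_<mark>_rep<r>.bed``
    (and ``.bedgraph`` when ``coverage``), a ``libsizes.tsv`` manifest,
    and ``counts_*.tsv`` / ``fpkm_*.tsv`` expression matrices.
    """
    from pathlib import Path

    from . import genomic_io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth, chip, expression = simulate(config, conditions, coverage)
    gio.write_gene_models(annotation, outdir / "genes.gff3")
    truth.df.to_csv(outdir / "truth.tsv", sep="\t")
    lib_rows = []
    for cond, samples in chip.items():
        for (mark, rep), sample in samples.items():
            stem = f"{cond}_{mark}_rep{rep}"
            gio.write_peaks(sample.peaks, outdir / f"{stem}.bed")
            if sample.track is not None:
                gio.write_coverage(sample.track, outdir / f"{stem}.bedgraph")
                lib_rows.append(
                    {
                        "sample_id": stem,
                        "total_mapped_tags": sample.track.total_mapped_tags,
                        "bin_width": sample.track.bin_width,
                    }
                )
    if lib_rows:
        pd.DataFrame(lib_rows).to_csv(outdir / "libsizes.tsv", sep="\t", index=False)
    for cond in conditions:
        gio.write_matrix(expression.counts[cond], outdir / f"counts_{cond}.tsv")
        gio.write_matrix(expression.fpkm[cond], outdir / f"fpkm_{cond}.tsv")
    for tp, counts in expression.timepoint_counts.items():
        gio.write_matrix(counts, outdir / f"counts_{tp}.tsv")


def simulate(
    config: SimulationConfig,
    conditions: tuple[str, ...] = CONDITIONS,
    coverage: bool = True,
):
    """Run the full generator; returns (annotation, truth, chip, expression)
    where chip maps condition -> {(mark, rep): ChipSample}."""
    annotation = generate_annotation(config)
    truth = generate_truth(config, annotation)
    chip = {
        cond: generate_chip(config, annotation, truth, cond, coverage=coverage)
        for cond in conditions
    }
    expression = generate_expression(config, truth, annotation)
    return annotation, truth, chip, expression
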