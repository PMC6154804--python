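"""ChIP tag quantification: per-gene TPM, genome-bin TPM, track
correlations, and metagene TSS profiles.

TPM here is the ChIP-enrichment density *tags per kilobase of region per
million mapped tags*:

    TPM(g) = C(g) * 1e9 / (L(g) * N)

with C the (fractionally apportioned) tag count in the gene's region, L
the region length in bases, and N the library's total mapped tags.  It
is unrelated to the RNA-seq transcripts-per-million unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import UPSTREAM_WIDTH, CoverageTrack, GenomeAnnotation

REGION_MODES = ("body", "body_plus_upstream2kb")


@dataclass
class MarkQuantification:
    """Per-gene TPM values for one mark over one region mode."""

    mark: str
    region_mode: str
    matrix: pd.DataFrame  # gene_id x sample_id


def region_tag_counts(
    track: CoverageTrack, regions: pd.DataFrame
) -> np.ndarray:
    """Tags overlapping each region, apportioned by overlap length."""
    counts = np.zeros(len(regions), dtype=np.float64)
    for chrom, grp in regions.groupby("chrom", sort=False):
        counts[grp.index.to_numpy()] = track.interval_sums(
            chrom, grp["start"].to_numpy(), grp["end"].to_numpy()
        )
    return counts


def compute_tpm(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    region_mode: str = "body",
    upstream: int = UPSTREAM_WIDTH,
) -> MarkQuantification:
    """Per-gene TPM of one track over gene body or body + 2 kb upstream.

    Genes whose region has zero length (cannot occur for ``body``) get a
    missing (NaN) TPM.
    """
    if region_mode not in REGION_MODES:
        raise ValueError(f"unknown region mode {region_mode!r}")
    regions = annotation.regions(region_mode, upstream).reset_index(drop=True)
    lengths = (regions["end"] - regions["start"]).to_numpy().astype(float)
    counts = region_tag_counts(track, regions)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = np.where(
            lengths > 0,
            counts * 1e9 / (lengths * track.total_mapped_tags),
            np.nan,
        )
    matrix = pd.DataFrame(
        {track.sample_id: tpm}, index=pd.Index(regions["gene_id"], name="gene_id")
    )
    return MarkQuantification(track.mark, region_mode, matrix)


def tpm_table(
    tracks: list[CoverageTrack],
    annotation: GenomeAnnotation,
    region_mode: str = "body",
) -> pd.DataFrame:
    """Gene x sample TPM matrix across several tracks of the same mark."""
    cols = [compute_tpm(t, annotation, region_mode).matrix for t in tracks]
    return pd.concat(cols, axis=1)


def bin_genome_tpm(
    track: CoverageTrack,
    chrom_sizes: dict[str, int],
    bin_width: int = 1000,
) -> pd.Series:
    """TPM per fixed genome bin, indexed by (chrom, bin start).

    Bins absent from the track are zero.  The conservation identity
    ``sum(bins) * bin_width * N / 1e9 == total binned tags`` holds
    exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    pieces = []
    for chrom in sorted(chrom_sizes):
        n_bins = -(-chrom_sizes[chrom] // bin_width)
        starts = np.arange(n_bins, dtype=np.int64) * bin_width
        counts = track.interval_sums(chrom, starts, starts + bin_width)
        idx = pd.MultiIndex.from_arrays(
            [[chrom] * n_bins, starts], names=["chrom", "start"]
        )
        pieces.append(pd.Series(counts, index=idx))
    binned = pd.concat(pieces) if pieces else pd.Series(dtype=float)
    return binned * 1e9 / (bin_width * track.total_mapped_tags)


def correlate_tracks(
    vectors: dict[str, pd.Series] | pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Symmetric correlation matrix between per-bin TPM vectors.

    Zero-variance vectors yield missing (NaN) off-diagonal entries; the
    diagonal is 1 by definition.
    """
    if not isinstance(vectors, pd.DataFrame):
        vectors = pd.DataFrame(vectors)
    if vectors.shape[1] < 2:
        raise ValueError("need at least two vectors")
    if vectors.shape[0] < 3:
        raise ValueError("need vectors of length >= 3")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    corr = vectors.corr(method=method)
    degenerate = vectors.std(ddof=0) == 0
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class MetageneProfile:
    """Mean TPM-scaled coverage over aligned gene coordinates.

    ``values`` is indexed by (zone, index): 2 kb of fixed 50-bp flank
    bins on either side and ``n_body_bins`` length-normalised body bins,
    all oriented 5'->3'.
    """

    mark: str
    values: pd.Series
    flank_bin_width: int
    n_body_bins: int
    n_genes: int


def metagene_profile(
    track: CoverageTrack,
    annotation: GenomeAnnotation,
    flank: int = 2000,
    flank_bin: int = 50,
    n_body_bins: int = 40,
) -> MetageneProfile:
    """Average TSS-to-TTS profile across genes.

    Flanks use fixed ``flank_bin``-bp bins; the body is split into
    ``n_body_bins`` equal-width bins so genes of unequal length can be
    averaged.  Bin values are TPM-scaled (tags * 1e9 / (bin length * N))
    and strand-oriented; flank bins that run off a chromosome end are
    dropped from the average.  Genes with body shorter than
    ``n_body_bins`` bases are excluded; with no qualifying gene this is
    an error.
    """
    if flank % flank_bin != 0:
        raise ValueError("flank must be a multiple of flank_bin")
    n_flank = flank // flank_bin
    df = annotation.df
    keep = (df["end"] - df["start"]) >= n_body_bins
    df = df[keep]
    if df.empty:
        raise ValueError("no genes with body length >= n_body_bins bases")
    N = track.total_mapped_tags
    n_tot = 2 * n_flank + n_body_bins
    acc = np.zeros((len(df), n_tot), dtype=np.float64)
    acc[:] = np.nan
    row = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        size = annotation.chrom_sizes[chrom]
        g_start = grp["start"].to_numpy().astype(float)
        g_end = grp["end"].to_numpy().astype(float)
        plus = (grp["strand"] == "+").to_numpy()
        m = len(grp)
        # genomic bin edges, 5'->3' per gene: upstream flank, body, downstream
        up_edges = np.linspace(-flank, 0, n_flank + 1)
        down_edges = np.linspace(0, flank, n_flank + 1)
        body_frac = np.linspace(0, 1, n_body_bins + 1)
        length = g_end - g_start
        edges = np.empty((m, n_tot + 1), dtype=np.float64)
        # + strand: start + [-flank..0], start + L*frac, end + [0..flank]
        e_plus = np.concatenate(
            [
                g_start[:, None] + up_edges[None, :],
                g_start[:, None] + length[:, None] * body_frac[None, 1:],
                g_end[:, None] + down_edges[None, 1:],
            ],
            axis=1,
        )
        # - strand: mirrored (5' is the right end), then genomic order restored
        e_minus = np.concatenate(
            [
                g_end[:, None] - up_edges[None, :],
                g_end[:, None] - length[:, None] * body_frac[None, 1:],
                g_start[:, None] - down_edges[None, 1:],
            ],
            axis=1,
        )
        edges[plus] = e_plus[plus]
        edges[~plus] = e_minus[~plus]
        lo = np.minimum(edges[:, :-1], edges[:, 1:])
        hi = np.maximum(edges[:, :-1], edges[:, 1:])
        valid = (lo >= 0) & (hi <= size)
        lo_c = np.clip(lo, 0, size)
        hi_c = np.clip(hi, 0, size)
        counts = track.interval_sums(
            chrom, lo_c.ravel(), hi_c.ravel()
        ).reshape(m, n_tot)
        widths = hi - lo
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = counts * 1e9 / (widths * N)
        scaled[~valid] = np.nan
        acc[row : row + m] = scaled
        row += m
    mean = np.nanmean(acc, axis=0)
    zones = (
        [("upstream", i) for i in range(n_flank)]
        + [("body", i) for i in range(n_body_bins)]
        + [("downstream", i) for i in range(n_flank)]
    )
    idx = pd.MultiIndex.from_tuples(zones, names=["zone", "index"])
    return MetageneProfile(track.mark, pd.Series(mean, index=idx), flank_bin, n_body_bins, len(df))


def pearson_r(x, y) -> float:
    """Plain Pearson correlation (NaN on zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])
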