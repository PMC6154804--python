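"""Strand-aware genomic interval primitives and flat-file I/O.

All internal coordinates are 0-based half-open ``[start, end)``.  GFF3's
1-based inclusive convention is converted exactly once, at the file
boundary, so that no downstream code ever has to reason about the
difference.  Peaks are stored merged (overlapping *and* bookended
intervals collapsed) and sorted, which lets every overlap query in the
package run as a binary search on disjoint intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical order of the three acylation marks used throughout.
MARKS = ("H3K9ac", "Kbu", "Kcr")

#: The eight mutually exclusive mark-combination labels.
COMBINATION_LABELS = (
    "none",
    "H3K9ac",
    "Kbu",
    "Kcr",
    "H3K9ac+Kbu",
    "H3K9ac+Kcr",
    "Kbu+Kcr",
    "H3K9ac+Kbu+Kcr",
)

VALID_STRANDS = ("+", "-", ".")
FEATURE_CLASSES = ("coding", "te_related")

#: Default width of the promoter/upstream window in bases.
UPSTREAM_WIDTH = 2000


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, line_number: int | None, message: str):
        self.path = str(path)
        self.line_number = line_number
        where = f"{path}" if line_number is None else f"{path}:{line_number}"
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return overlaps(self, other)


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneModel:
    """A gene: one interval plus a coarse feature class.

    ``feature_class`` separates ordinary protein-coding genes from
    transposable-element-related gene models, which behave very
    differently under active chromatin marks.
    """

    gene_id: str
    interval: Interval
    feature_class: str = "coding"

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"invalid feature_class {self.feature_class!r}")

    @property
    def tss(self) -> int:
        """Transcription start site (strand aware)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end


class GenomeAnnotation:
    """A set of gene models plus chromosome lengths.

    The genes are exposed both as :class:`GeneModel` objects and as a
    DataFrame (``.df``) with columns gene_id, chrom, start, end, strand,
    feature_class — the vectorised substrate for quantification and
    mark calling.
    """

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Mapping[str, int]):
        genes = list(genes)
        self.chrom_sizes = dict(chrom_sizes)
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.interval.chrom)
            if size is None:
                raise ValueError(
                    f"gene {g.gene_id}: unknown chromosome {g.interval.chrom!r}"
                )
            if g.interval.end > size:
                raise ValueError(
                    f"gene {g.gene_id}: interval end {g.interval.end} exceeds "
                    f"{g.interval.chrom} length {size}"
                )
        self._genes = genes
        self.df = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "chrom": [g.interval.chrom for g in genes],
                "start": np.asarray([g.interval.start for g in genes], dtype=np.int64),
                "end": np.asarray([g.interval.end for g in genes], dtype=np.int64),
                "strand": [g.interval.strand for g in genes],
                "feature_class": [g.feature_class for g in genes],
            }
        )

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.df["gene_id"])

    def gene_lengths(self) -> pd.Series:
        df = self.df
        return pd.Series(
            (df["end"] - df["start"]).to_numpy(), index=df["gene_id"], name="length"
        )

    def regions(self, mode: str = "body", upstream: int = UPSTREAM_WIDTH) -> pd.DataFrame:
        """Per-gene analysis region as a frame (chrom, start, end).

        ``mode`` is ``"body"`` or ``"body_plus_upstream2kb"``; the
        upstream extension is strand aware and clipped at chromosome
        edges.
        """
        df = self.df
        start = df["start"].to_numpy().copy()
        end = df["end"].to_numpy().copy()
        if mode == "body_plus_upstream2kb":
            plus = (df["strand"] == "+").to_numpy()
            sizes = df["chrom"].map(self.chrom_sizes).to_numpy()
            start[plus] = np.maximum(0, start[plus] - upstream)
            end[~plus] = np.minimum(sizes[~plus], end[~plus] + upstream)
        elif mode != "body":
            raise ValueError(f"unknown region mode {mode!r}")
        return pd.DataFrame(
            {"gene_id": df["gene_id"], "chrom": df["chrom"], "start": start, "end": end}
        )


def upstream_region(
    gene: GeneModel, width: int, chrom_sizes: Mapping[str, int]
) -> Interval | None:
    """Strand-aware upstream window of a gene, clipped at chromosome edges.

    Returns None when the window is empty (gene flush against the edge).
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    iv = gene.interval
    if iv.strand == "+":
        s, e = max(0, iv.start - width), iv.start
    else:
        s, e = iv.end, min(chrom_sizes[iv.chrom], iv.end + width)
    if s >= e:
        return None
    return Interval(iv.chrom, s, e, ".")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping or bookended intervals per chromosome."""
    if df.empty:
        return pd.DataFrame({"chrom": [], "start": [], "end": []}).astype(
            {"chrom": str, "start": np.int64, "end": np.int64}
        )
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom)
                out_start.append(cur_s)
                out_end.append(cur_e)
                cur_s, cur_e = s, e
        out_chrom.append(chrom)
        out_start.append(cur_s)
        out_end.append(cur_e)
    return pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.asarray(out_start, dtype=np.int64),
            "end": np.asarray(out_end, dtype=np.int64),
        }
    )


class PeakSet:
    """Merged, sorted peak intervals for one sample (mark × replicate)."""

    def __init__(
        self,
        sample_id: str,
        mark: str,
        replicate: int,
        peaks: pd.DataFrame | Sequence[Interval],
    ):
        if mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
        if replicate < 1:
            raise ValueError("replicate index must be >= 1")
        self.sample_id = sample_id
        self.mark = mark
        self.replicate = replicate
        if not isinstance(peaks, pd.DataFrame):
            peaks = pd.DataFrame(
                {
                    "chrom": [p.chrom for p in peaks],
                    "start": [p.start for p in peaks],
                    "end": [p.end for p in peaks],
                }
            )
        peaks = peaks[["chrom", "start", "end"]].copy()
        if len(peaks) and not (peaks["start"] < peaks["end"]).all():
            bad = peaks[~(peaks["start"] < peaks["end"])].iloc[0]
            raise ValueError(
                f"peak with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        self.peaks = merge_intervals(peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[Interval]:
        return [
            Interval(r.chrom, int(r.start), int(r.end), ".")
            for r in self.peaks.itertuples()
        ]


@dataclass
class CoverageTrack:
    """Fixed-width binned tag counts for one sample.

    ``values`` maps chromosome name to a dense array of per-bin tag
    counts (fractional counts allowed: bedGraph records are apportioned
    into bins proportionally to overlap length).  Chromosomes with no
    signal may be absent and are treated as zero.  ``total_mapped_tags``
    is the library size N in the TPM formula and need not equal the sum
    of binned counts.
    """

    sample_id: str
    mark: str
    replicate: int
    bin_width: int
    total_mapped_tags: float
    values: dict[str, np.ndarray] = field(default_factory=dict)
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.total_mapped_tags <= 0:
            raise ValueError("total_mapped_tags must be > 0")

    def _cumulative(self, chrom: str) -> np.ndarray | None:
        """Prefix-sum of bin counts; F[i] = tags in bins [0, i)."""
        if chrom not in self.values:
            return None
        F = self._cum.get(chrom)
        if F is None:
            F = np.concatenate(([0.0], np.cumsum(self.values[chrom], dtype=np.float64)))
            self._cum[chrom] = F
        return F

    def interval_sums(self, chrom: str, starts, ends) -> np.ndarray:
        """Tag counts in ``[start, end)`` windows, apportioning partially
        overlapped bins by overlap fraction (tags uniform within a bin)."""
        starts = np.asarray(starts, dtype=np.float64)
        ends = np.asarray(ends, dtype=np.float64)
        F = self._cumulative(chrom)
        if F is None:
            return np.zeros(starts.shape, dtype=np.float64)
        grid = np.arange(F.size, dtype=np.float64)
        lo = np.interp(np.clip(starts / self.bin_width, 0, F.size - 1), grid, F)
        hi = np.interp(np.clip(ends / self.bin_width, 0, F.size - 1), grid, F)
        return hi - lo

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.interval_sums(chrom, [start], [end])[0])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GFF_COLUMNS = (
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
)


def read_gene_models(
    path, te_keywords: Sequence[str] = ("transposon", "transposable")
) -> GenomeAnnotation:
    """Read gene records from a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3 coordinates (1-based, inclusive) are converted to the internal
    0-based half-open convention.  A gene is classed ``te_related`` when
    any of ``te_keywords`` occurs (case-insensitively) in its attribute
    column.  Chromosome lengths come from ``##sequence-region`` pragmas
    when present, otherwise from the maximal gene end per chromosome.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    keywords = [k.lower() for k in te_keywords]
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ParseError(path, lineno, "malformed ##sequence-region pragma")
                chrom_sizes[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    path, lineno, f"expected 9 tab-separated fields, got {len(fields)}"
                )
            rec = dict(zip(_GFF_COLUMNS, fields))
            if rec["type"] != "gene":
                continue
            try:
                start1 = int(rec["start"])
                end1 = int(rec["end"])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric coordinate") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(path, lineno, f"invalid coordinates {start1}..{end1}")
            attrs = dict(
                kv.split("=", 1) for kv in rec["attributes"].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if not gene_id:
                raise ParseError(path, lineno, "gene record without ID attribute")
            if gene_id in seen_ids:
                raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
            seen_ids.add(gene_id)
            attr_lower = rec["attributes"].lower()
            fclass = (
                "te_related"
                if any(k in attr_lower for k in keywords)
                else "coding"
            )
            try:
                gene = GeneModel(
                    gene_id,
                    Interval(rec["seqid"], start1 - 1, end1, rec["strand"]),
                    fclass,
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            genes.append(gene)
    for g in genes:
        chrom = g.interval.chrom
        chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), g.interval.end)
    return GenomeAnnotation(genes, chrom_sizes)


def write_gene_models(annotation: GenomeAnnotation, path) -> None:
    """Write an annotation as GFF3 (restores 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        for g in annotation:
            iv = g.interval
            attrs = f"ID={g.gene_id}"
            if g.feature_class == "te_related":
                attrs += ";Note=transposable element"
            fh.write(
                f"{iv.chrom}\t.\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def read_peaks(path, sample_id: str, mark: str, replicate: int) -> PeakSet:
    """Read a BED3(+) peak file (0-based half-open) into a merged PeakSet."""
    path = Path(path)
    rows: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "fewer than 3 BED fields")
            try:
                s, e = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric coordinate") from None
            if s >= e:
                raise ParseError(path, lineno, f"start {s} >= end {e}")
            if s < 0:
                raise ParseError(path, lineno, f"negative start {s}")
            rows.append((fields[0], s, e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(sample_id, mark, replicate, df)


def write_peaks(peaks: PeakSet, path) -> None:
    peaks.peaks.to_csv(path, sep="\t", header=False, index=False)


def read_coverage(
    path,
    sample_id: str,
    mark: str,
    replicate: int,
    bin_width: int,
    total_mapped_tags: float,
    chrom_sizes: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Read a bedGraph into fixed-width bins.

    Each record's value is treated as a per-``bin_width`` density over
    its span: a bin receives ``value * overlap / bin_width``, so a
    record exactly tiling k bins adds ``value`` to each.
    """
    path = Path(path)
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, "fewer than 4 bedGraph fields")
            chrom = fields[0]
            try:
                s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric field") from None
            if s >= e or s < 0:
                raise ParseError(path, lineno, f"invalid span [{s}, {e})")
            if v < 0:
                raise ParseError(path, lineno, f"negative value {v}")
            if chrom_sizes is not None:
                size = chrom_sizes.get(chrom)
                if size is None or e > size:
                    raise ParseError(
                        path, lineno, f"record beyond length of {chrom!r}"
                    )
            per_chrom.setdefault(chrom, []).append((s, e, v))
    values: dict[str, np.ndarray] = {}
    for chrom, recs in per_chrom.items():
        if chrom_sizes is not None:
            n_bins = -(-chrom_sizes[chrom] // bin_width)
        else:
            n_bins = -(-max(e for _, e, _ in recs) // bin_width)
        arr = np.zeros(n_bins, dtype=np.float64)
        recs_a = np.asarray(recs, dtype=np.float64)
        s_a, e_a, v_a = recs_a[:, 0], recs_a[:, 1], recs_a[:, 2]
        aligned = (s_a % bin_width == 0) & (e_a - s_a == bin_width)
        idx = (s_a[aligned] / bin_width).astype(np.int64)
        np.add.at(arr, idx, v_a[aligned])
        for s, e, v in recs_a[~aligned]:
            b0 = int(s // bin_width)
            b1 = int(-(-e // bin_width))
            edges = np.arange(b0, b1 + 1, dtype=np.float64) * bin_width
            lo = np.maximum(edges[:-1], s)
            hi = np.minimum(edges[1:], e)
            arr[b0:b1] += v * (hi - lo) / bin_width
        values[chrom] = arr
    return CoverageTrack(
        sample_id, mark, replicate, bin_width, total_mapped_tags, values
    )


def write_coverage(track: CoverageTrack, path) -> None:
    """Write the binned track as bedGraph (zero bins omitted)."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            for i in np.nonzero(arr)[0]:
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{arr[i]:g}\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a gene × sample TSV matrix (first column gene_id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a two-column TSV (term_id, gene_id) into term → gene-set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"])
    return {term: set(grp["gene_id"]) for term, grp in df.groupby("term_id")}
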