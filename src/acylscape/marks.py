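"""Marked-gene calling from replicated peaks and combination profiling.

A gene is *marked* by a modification when a peak overlaps its gene body
or its 2-kb strand-aware upstream window **in both ChIP replicates**.
The three per-mark boolean calls partition the gene universe into eight
mutually exclusive combination categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import (
    COMBINATION_LABELS,
    MARKS,
    UPSTREAM_WIDTH,
    GenomeAnnotation,
    PeakSet,
)


@dataclass
class MarkStatus:
    """Per-gene boolean marked calls for one mark."""

    mark: str
    marked: pd.Series  # bool, indexed by gene_id

    @property
    def n_marked(self) -> int:
        return int(self.marked.sum())


@dataclass
class CombinationProfile:
    """Per-gene combination label; labels partition the universe."""

    labels: pd.Series  # str, indexed by gene_id

    def counts(self) -> pd.Series:
        c = self.labels.value_counts()
        return c.reindex(COMBINATION_LABELS, fill_value=0)

    def genes_with_label(self, label: str) -> set[str]:
        return set(self.labels.index[self.labels == label])


def _regions_overlap_peaks(regions: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Vectorised any-overlap test of regions against merged sorted peaks."""
    hit = np.zeros(len(regions), dtype=bool)
    if peaks.empty:
        return hit
    for chrom, grp in regions.groupby("chrom", sort=False):
        p = peaks[peaks["chrom"] == chrom]
        if p.empty:
            continue
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()  # disjoint sorted -> ends sorted too
        gs = grp["start"].to_numpy()
        ge = grp["end"].to_numpy()
        # a peak overlaps [gs, ge) iff its start < ge and its end > gs
        n_start_before = np.searchsorted(starts, ge, side="left")
        n_end_at_or_before = np.searchsorted(ends, gs, side="right")
        hit[grp.index.to_numpy()] = n_start_before > n_end_at_or_before
    return hit


def call_marked_genes(
    peaks_rep1: PeakSet,
    peaks_rep2: PeakSet,
    annotation: GenomeAnnotation,
    upstream: int = UPSTREAM_WIDTH,
) -> MarkStatus:
    """AND-of-replicates marked-gene rule over body + upstream window."""
    if peaks_rep1.mark != peaks_rep2.mark:
        raise ValueError(
            f"replicate peak sets have different marks: "
            f"{peaks_rep1.mark!r} vs {peaks_rep2.mark!r}"
        )
    regions = annotation.regions("body_plus_upstream2kb", upstream).reset_index(drop=True)
    hit1 = _regions_overlap_peaks(regions, peaks_rep1.peaks)
    hit2 = _regions_overlap_peaks(regions, peaks_rep2.peaks)
    marked = pd.Series(hit1 & hit2, index=pd.Index(regions["gene_id"], name="gene_id"))
    return MarkStatus(peaks_rep1.mark, marked)


def classify_combinations(
    status_k9ac: MarkStatus, status_kbu: MarkStatus, status_kcr: MarkStatus
) -> CombinationProfile:
    """Label every gene with its 8-way mark combination."""
    statuses = {s.mark: s for s in (status_k9ac, status_kbu, status_kcr)}
    if set(statuses) != set(MARKS):
        raise ValueError(f"need one MarkStatus per mark {MARKS}")
    idx = statuses[MARKS[0]].marked.index
    for mark in MARKS[1:]:
        if not statuses[mark].marked.index.equals(idx):
            raise ValueError("mark statuses cover different gene universes")
    parts = [
        np.where(statuses[mark].marked.to_numpy(), mark, "") for mark in MARKS
    ]
    labels = ["+".join(p for p in triple if p) or "none" for triple in zip(*parts)]
    return CombinationProfile(pd.Series(labels, index=idx, name="label"))


def marginal_counts(profile: CombinationProfile) -> dict:
    """Per-mark totals, pairwise/triple overlaps, and co-marking rates.

    Totals are sums over the combination categories containing the mark,
    so they are consistent with the partition by construction.
    """
    counts = profile.counts()

    def total(*marks: str) -> int:
        return int(
            sum(
                n
                for label, n in counts.items()
                if all(m in label.split("+") for m in marks)
            )
        )

    totals = {m: total(m) for m in MARKS}
    pairwise = {
        (a, b): total(a, b)
        for i, a in enumerate(MARKS)
        for b in MARKS[i + 1 :]
    }
    triple = total(*MARKS)
    pct_comarked = {
        m: (100.0 * triple / totals[m]) if totals[m] else float("nan") for m in MARKS
    }
    return {
        "category_counts": counts.to_dict(),
        "totals": totals,
        "pairwise": pairwise,
        "triple": triple,
        "pct_comarked_by_other_two": pct_comarked,
    }


def peak_context_distribution(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    upstream: int = UPSTREAM_WIDTH,
) -> pd.Series:
    """Proportion of peaks in genic / promoter / intergenic context.

    Each peak is assigned once with priority genic > promoter >
    intergenic; genic and promoter assignments carry the feature class
    (coding vs te_related) of the maximally overlapped gene (ties broken
    in favour of coding).  Proportions sum to 1.
    """
    keys = [
        ("genic", "coding"),
        ("genic", "te_related"),
        ("promoter", "coding"),
        ("promoter", "te_related"),
        ("intergenic", "."),
    ]
    n_peaks = len(peaks.peaks)
    out = pd.Series(0.0, index=pd.MultiIndex.from_tuples(keys, names=["context", "feature_class"]))
    if n_peaks == 0:
        return out

    def by_chrom(regions: pd.DataFrame) -> dict:
        """chrom -> (starts, ends, cummax_ends, classes), start-sorted."""
        index = {}
        for chrom, grp in regions.sort_values(["chrom", "start"]).groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            index[chrom] = (
                starts,
                ends,
                np.maximum.accumulate(ends),
                grp["feature_class"].to_numpy(),
            )
        return index

    def best_class(index: dict, chrom, s, e) -> str | None:
        entry = index.get(chrom)
        if entry is None:
            return None
        starts, ends, cummax, classes = entry
        hi = np.searchsorted(starts, e, side="left")
        lo = np.searchsorted(cummax, s, side="right")
        if lo >= hi:
            return None
        ov = np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s)
        best = ov.max()
        if best <= 0:
            return None
        cand = classes[lo:hi][ov == best]
        return "coding" if "coding" in cand else str(cand[0])

    adf = annotation.df
    bodies = by_chrom(adf[["chrom", "start", "end", "feature_class"]])
    plus = adf["strand"] == "+"
    sizes = adf["chrom"].map(annotation.chrom_sizes)
    prom = pd.DataFrame(
        {
            "chrom": adf["chrom"],
            "start": np.where(plus, np.maximum(0, adf["start"] - upstream), adf["end"]),
            "end": np.where(plus, adf["start"], np.minimum(sizes, adf["end"] + upstream)),
            "feature_class": adf["feature_class"],
        }
    )
    promoters = by_chrom(prom[prom["start"] < prom["end"]])
    for r in peaks.peaks.itertuples():
        cls = best_class(bodies, r.chrom, r.start, r.end)
        if cls is not None:
            out[("genic", cls)] += 1
            continue
        cls = best_class(promoters, r.chrom, r.start, r.end)
        if cls is not None:
            out[("promoter", cls)] += 1
        else:
            out[("intergenic", ".")] += 1
    return out / n_peaks
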