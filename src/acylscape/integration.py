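"""Acylation-proportion statistics and mark/expression integration.

The central statistic is the per-gene *acylation proportion*: each
mark's gene-body TPM divided by the summed body TPM of the three marks
(H3K9ac + Kbu + Kcr).  The three proportions live on the 2-simplex, so
any between-condition change is zero-sum across marks — a gene can only
trade acetylation share against acylation share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import MARKS
from .quantify import pearson_r

LOG_OFFSET = 0.001  # expression transform: log10(FPKM + 0.001)


@dataclass
class ProportionTable:
    """Per-gene simplex of mark proportions plus total acylation TPM.

    ``table`` columns: ``p_H3K9ac, p_Kbu, p_Kcr, total``.  Proportions
    are jointly missing exactly when the total acylation TPM is zero.
    """

    table: pd.DataFrame

    @property
    def defined(self) -> pd.Series:
        return self.table["total"] > 0


def acylation_proportions(
    tpm_k9ac: pd.Series, tpm_kbu: pd.Series, tpm_kcr: pd.Series
) -> ProportionTable:
    """Per-mark share of each gene's total acylation TPM.

    Inputs are replicate-averaged body TPM per gene (same index).
    Genes with zero total are flagged missing rather than divided.
    """
    tpms = {"H3K9ac": tpm_k9ac, "Kbu": tpm_kbu, "Kcr": tpm_kcr}
    idx = tpm_k9ac.index
    for mark, s in tpms.items():
        if not s.index.equals(idx):
            raise ValueError("mark TPM series cover different gene universes")
        if (s < 0).any():
            raise ValueError(f"negative TPM values for {mark}")
    total = sum(tpms.values())
    out = pd.DataFrame(index=idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        for mark in MARKS:
            out[f"p_{mark}"] = np.where(total > 0, tpms[mark] / total, np.nan)
    out["total"] = total
    return ProportionTable(out)


def proportion_change(
    props_control: ProportionTable,
    props_treated: ProportionTable,
    deg: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene proportion deltas and summaries over up/down DEGs.

    Returns ``(delta, summary)``.  ``delta`` has one Δp column per mark
    (treated − control) over genes defined in both tables; genes missing
    in either are excluded (their number is recorded in
    ``delta.attrs["n_excluded"]``).  ``summary`` gives median and mean
    Δp per mark within the up- and down-called DEG groups when a
    differential-expression result is supplied.
    """
    a = props_control.table
    b = props_treated.table
    if not a.index.equals(b.index):
        raise ValueError("proportion tables cover different gene universes")
    ok = props_control.defined & props_treated.defined
    delta = pd.DataFrame(index=a.index[ok])
    for mark in MARKS:
        delta[f"dp_{mark}"] = (b.loc[ok, f"p_{mark}"] - a.loc[ok, f"p_{mark}"])
    delta.attrs["n_excluded"] = int((~ok).sum())
    rows = []
    if deg is not None:
        for direction in ("up", "down"):
            genes = deg.index[deg["call"] == direction]
            sub = delta.reindex(genes.intersection(delta.index))
            for mark in MARKS:
                rows.append(
                    {
                        "direction": direction,
                        "mark": mark,
                        "n": len(sub),
                        "median_dp": sub[f"dp_{mark}"].median(),
                        "mean_dp": sub[f"dp_{mark}"].mean(),
                    }
                )
    summary = pd.DataFrame(rows)
    return delta, summary


def transform_expression(fpkm: pd.Series) -> pd.Series:
    """log10(FPKM + 0.001); FPKM 0 maps to -3."""
    if (fpkm < 0).any():
        raise ValueError("negative FPKM values")
    return np.log10(fpkm + LOG_OFFSET)


def _summaries(values: pd.Series) -> dict:
    return {
        "n": int(values.size),
        "median": values.median() if values.size else np.nan,
        "q1": values.quantile(0.25) if values.size else np.nan,
        "q3": values.quantile(0.75) if values.size else np.nan,
    }


def expression_by_category(fpkm: pd.Series, profile) -> pd.DataFrame:
    """Distribution of log10(FPKM+0.001) per mark-combination category."""
    expr = transform_expression(fpkm)
    rows = []
    for label in profile.counts().index:
        genes = profile.labels.index[profile.labels == label]
        rows.append({"label": label, **_summaries(expr.reindex(genes).dropna())})
    return pd.DataFrame(rows).set_index("label")


def expression_by_proportion_band(
    fpkm: pd.Series,
    props: ProportionTable,
    n_bands: int = 4,
    mark: str = "H3K9ac",
) -> pd.DataFrame:
    """Expression summaries across quantile bands of one mark's proportion.

    Genes are split into ``n_bands`` quantile bands of ``p_<mark>``
    (missing proportions dropped); each band's log10(FPKM+0.001)
    distribution is summarised.  Degenerate proportion distributions
    that cannot produce the requested number of distinct bands raise.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    p = props.table.loc[props.defined, f"p_{mark}"].dropna()
    if len(p) < n_bands:
        raise ValueError("fewer non-missing genes than bands")
    try:
        bands = pd.qcut(p, n_bands, labels=False, duplicates="raise")
    except ValueError as exc:
        raise ValueError(
            f"cannot form {n_bands} distinct proportion bands: {exc}"
        ) from None
    expr = transform_expression(fpkm)
    rows = []
    for band in range(n_bands):
        genes = p.index[bands == band]
        rows.append({"band": band, **_summaries(expr.reindex(genes).dropna())})
    return pd.DataFrame(rows).set_index("band")


def total_acylation_by_category(
    tpm_k9ac: pd.Series, tpm_kbu: pd.Series, tpm_kcr: pd.Series, profile
) -> pd.DataFrame:
    """Distribution of summed three-mark body TPM per combination category."""
    total = tpm_k9ac + tpm_kbu + tpm_kcr
    rows = []
    for label in profile.counts().index:
        genes = profile.labels.index[profile.labels == label]
        rows.append({"label": label, **_summaries(total.reindex(genes).dropna())})
    return pd.DataFrame(rows).set_index("label")


def change_correlation(
    diffexpr: pd.DataFrame, diffmod: pd.DataFrame, degs_only: bool = True
) -> float:
    """Pearson r between expression log2FC and mark log2FC.

    Computed over called DEGs by default (the published contrast);
    returns NaN when fewer than 3 genes or zero variance.
    """
    genes = diffexpr.index
    if degs_only:
        genes = genes[diffexpr["call"] != "unchanged"]
    genes = genes.intersection(diffmod.index)
    if len(genes) < 3:
        return float("nan")
    x = diffexpr.loc[genes, "log2fc"].to_numpy()
    y = diffmod.loc[genes, "log2fc"].to_numpy()
    return pearson_r(x, y)
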