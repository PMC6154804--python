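"""Gene-set and mark-combination enrichment with FDR control.

Two test routes are provided: the exact one-sided hypergeometric tail
for combination-category enrichment within a gene subset, and Pearson's
chi-squared (1 df, no continuity correction) for GO-style term
enrichment, adjusted by Benjamini-Hochberg across terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (NaN) are excluded from the number of tests m and
    propagate as NaN.  Raises on p outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def hypergeom_enrichment_p(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) — upper tail at the
    observed overlap, the standard over-representation p-value."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _result_row(term, k: int, n: int, K: int, N: int, p: float) -> dict:
    fold = (k / n) / (K / N) if n and K else np.nan
    return {"term": term, "k": k, "n": n, "K": K, "N": N, "fold": fold, "p_value": p}


def combination_enrichment(
    profile,
    subset: set[str],
    alpha: float = 0.01,
    method: str = "hypergeometric",
) -> pd.DataFrame:
    """Enrichment of each mark-combination category within a gene subset.

    ``profile`` is a :class:`~acylscape.marks.CombinationProfile`; the
    universe is its gene index.  The fold is (k/n)/(K/N), i.e. the
    category's share of the subset relative to its genome-wide share.
    ``method`` may be "hypergeometric" (exact tail, default) or
    "chi2" (Pearson chi-squared, for parity with the GO-style route).
    """
    universe = set(profile.labels.index)
    if not subset:
        raise ValueError("subset is empty")
    extra = subset - universe
    if extra:
        raise ValueError(f"subset contains {len(extra)} genes outside the universe")
    N = len(universe)
    n = len(subset)
    rows = []
    sub_labels = profile.labels.loc[sorted(subset)]
    for label, K in profile.counts().items():
        k = int((sub_labels == label).sum())
        if method == "hypergeometric":
            p = hypergeom_enrichment_p(N, int(K), n, k)
        elif method == "chi2":
            p = _chi2_2x2(k, n - k, int(K) - k, N - n - int(K) + k)[1]
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(_result_row(label, k, n, int(K), N, p))
    res = pd.DataFrame(rows).set_index("term")
    res["significant"] = res["p_value"] < alpha
    return res


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared statistic and p for a 2x2 table (1 df, no
    continuity correction).  Zero-margin tables give (nan, nan)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    n = table.sum()
    stat = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    return float(stat), float(stats.chi2.sf(stat, df=1))


def gene_set_enrichment(
    gene_sets: dict[str, set[str]],
    subset: set[str],
    universe: set[str],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Term enrichment by Pearson's chi-squared with BH FDR across terms.

    Each term's 2x2 table crosses subset membership with term
    membership over the universe; gene sets are first intersected with
    the universe.  Terms with a zero margin get missing p-values (not
    zero) and are excluded from the FDR adjustment.
    """
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    N = len(universe)
    n = len(subset)
    rows = []
    for term, genes in gene_sets.items():
        genes = genes & universe
        K = len(genes)
        k = len(genes & subset)
        stat, p = _chi2_2x2(k, n - k, K - k, N - n - K + k)
        row = _result_row(term, k, n, K, N, p)
        row["chi2"] = stat
        rows.append(row)
    res = pd.DataFrame(rows).set_index("term")
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    res["significant"] = res["fdr"] < fdr_cutoff
    return res
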