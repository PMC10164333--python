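"""Nonparametric repeated-measures statistics over condition-level metrics.

The analysis chain screens each condition with Shapiro-Wilk, tests for any
difference across conditions with the Friedman rank test (complete cases),
follows up with pairwise Wilcoxon signed-rank tests using Pratt's treatment
of zero differences, and controls the family-wise error rate with the
Holm-Bonferroni step-down procedure.

``wilcoxon_pratt`` is implemented here rather than taken from scipy because
the exact null distribution with Pratt zeros (zeros ranked, then dropped
from the signed sums) is needed for the small samples this design produces;
it is cross-checked against exhaustive sign-flip enumeration in the test
suite.  Friedman is likewise computed from the rank formula (average ranks
for ties) so that two-condition tables are allowed; it agrees with
``scipy.stats.friedmanchisquare`` for three or more conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = ["normality_screen", "friedman", "wilcoxon_pratt", "holm_bonferroni",
           "pairwise_wilcoxon_holm", "StatResult"]

#: exact enumeration of the Wilcoxon null up to this many nonzero differences
EXACT_N = 12


@dataclass
class StatResult:
    name: str
    statistic: float
    pvalue: float
    note: str = ""


def normality_screen(table: pd.DataFrame, min_n: int = 3) -> pd.Series:
    """Shapiro-Wilk p-value per condition column.

    Columns with fewer than ``min_n`` non-missing values, or degenerate
    (constant) columns, are skipped and reported as NaN.
    """
    out = {}
    for col in table.columns:
        vals = table[col].dropna().to_numpy(dtype=float)
        if vals.shape[0] < min_n or np.ptp(vals) == 0:
            out[col] = np.nan
        else:
            out[col] = sstats.shapiro(vals).pvalue
    return pd.Series(out, name="shapiro_p")


def friedman(table: pd.DataFrame) -> StatResult:
    """Friedman rank test across conditions (rows = participants).

    Rows with any missing cell are excluded (listwise deletion).  Uses
    average ranks for ties with the standard tie correction; the p-value
    comes from the chi-square distribution with k-1 degrees of freedom.
    """
    data = table.dropna(axis=0, how="any").to_numpy(dtype=float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 complete cases")
    ranks = np.apply_along_axis(sstats.rankdata, 1, data)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj ** 2) - 3.0 * n * (k + 1)
    # tie correction: per row, sum of (t^3 - t) over tied groups
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += np.sum(counts ** 3 - counts)
    denom = 1.0 - tie_sum / (n * k * (k ** 2 - 1))
    if denom <= 0:
        # all rows fully tied: no evidence of any difference
        return StatResult("friedman", 0.0, 1.0, note="all rows tied")
    stat /= denom
    p = float(sstats.chi2.sf(stat, k - 1))
    return StatResult("friedman", float(stat), p)


def _wplus_distribution(ranks2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ over sign flips.

    ``ranks2`` are the (possibly tied, half-integer) ranks doubled so they
    are integers; returns (support/2, counts).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    support = np.arange(total + 1) / 2.0
    return support, counts


def wilcoxon_pratt(x, y=None) -> StatResult:
    """Wilcoxon signed-rank test with Pratt's zero method, two-sided.

    Zero differences are kept while ranking the absolute differences and then
    dropped from the signed rank sums.  For up to 12 nonzero differences the
    p-value is exact (enumeration over sign assignments of the nonzero
    ranks); beyond that, the normal approximation with the Pratt zero
    correction and tie correction is used.  The reported statistic is W+, the
    sum of positive ranks.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.ndim != 1 or d.shape[0] < 3:
        raise ValueError("need at least 3 paired values")
    n = d.shape[0]
    ranks = sstats.rankdata(np.abs(d))       # zeros included in the ranking
    nonzero = d != 0
    m = int(nonzero.sum())
    if m == 0:
        return StatResult("wilcoxon_pratt", 0.0, 1.0, note="all differences zero")
    r_nz = ranks[nonzero]
    w_plus = float(r_nz[d[nonzero] > 0].sum())

    if m <= EXACT_N:
        support, counts = _wplus_distribution(np.round(2 * r_nz).astype(int))
        total = counts.sum()
        lo = counts[support <= w_plus + 1e-9].sum() / total
        hi = counts[support >= w_plus - 1e-9].sum() / total
        p = min(2.0 * min(lo, hi), 1.0)
        return StatResult("wilcoxon_pratt", w_plus, float(p), note="exact")

    # normal approximation with Pratt zero correction (zeros hold the lowest
    # ranks) and tie correction
    z = n - m
    mu = (n * (n + 1) - z * (z + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - z * (z + 1) * (2 * z + 1)) / 24.0
    _, tie_counts = np.unique(ranks[nonzero], return_counts=True)
    var -= np.sum(tie_counts ** 3 - tie_counts) / 48.0
    if var <= 0:
        return StatResult("wilcoxon_pratt", w_plus, 1.0, note="degenerate variance")
    zstat = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
    p = float(2.0 * sstats.norm.sf(abs(zstat)))
    return StatResult("wilcoxon_pratt", w_plus, min(p, 1.0), note="normal approx")


def holm_bonferroni(pvalues, alpha: float = 0.05) -> pd.DataFrame:
    """Holm-Bonferroni step-down correction.

    Returns a frame with raw p, adjusted p (monotone non-decreasing in rank
    order) and rejection flags at ``alpha``.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("empty p-value list")
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="holm")
    return pd.DataFrame({"p_raw": pvalues, "p_holm": p_adj, "reject": reject})


def pairwise_wilcoxon_holm(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Wilcoxon-Pratt comparisons between condition columns,
    Holm-corrected within this family (pairwise deletion of missing cells)."""
    cols = list(table.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            sub = table[[cols[i], cols[j]]].dropna()
            res = wilcoxon_pratt(sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy())
            rows.append({"a": cols[i], "b": cols[j], "n": len(sub),
                         "W": res.statistic, "p_raw": res.pvalue, "note": res.note})
    out = pd.DataFrame(rows)
    if not out.empty:
        adj = holm_bonferroni(out["p_raw"].to_numpy(), alpha)
        out["p_holm"] = adj["p_holm"].to_numpy()
        out["reject"] = adj["reject"].to_numpy()
    return out
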