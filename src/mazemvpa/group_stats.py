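"""Rank-based group statistics for procedure and behaviour comparisons.

All between-procedure comparisons are non-parametric: Friedman tests across
subjects for an omnibus effect of condition, paired Wilcoxon signed-rank
tests (Bonferroni-corrected) post hoc, and Spearman correlations for
brain-behaviour associations.  Support-vector class proportions are related
to class accuracies with a full grid of Spearman correlations whose signs
diagnose how SVM sparsity interacts with class imbalance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def friedman_test(table: np.ndarray) -> tuple[float, float]:
    """Friedman test over a subjects x conditions matrix.

    Within-subject mid-ranks with tie correction, chi-square approximation.
    A table whose rows are all internally constant carries no rank
    information; it returns (0.0, 1.0) — the no-effect limit.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 conditions")
    if table.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if all(len(np.unique(row)) == 1 for row in table):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*table.T)
    return float(stat), float(p)


def wilcoxon_paired(
    x, y, correction_family_size: int = 1
) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank test with Bonferroni adjustment.

    Zero differences are dropped (Wilcoxon's original policy); the exact
    null distribution is used for n <= 25 without ties, the normal
    approximation otherwise.  Returns (statistic, raw p, adjusted p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; test is degenerate")
    n = len(d)
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    adj = min(1.0, res.pvalue * correction_family_size)
    return float(res.statistic), float(res.pvalue), float(adj)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def sv_accuracy_association(
    sv_proportions: pd.DataFrame, class_accuracies: pd.DataFrame
) -> pd.DataFrame:
    """Spearman grid relating SV class proportions to class accuracies.

    Both inputs are subjects x columns tables with matched rows.  The report
    holds one row per (SV measure, class accuracy) pairing with rho, p and
    the sign, for consistency inspection against the expectation that a
    larger majority-class SV share depresses minority-class accuracy.
    """
    if len(sv_proportions) != len(class_accuracies):
        raise ValueError("subject rows of the two tables must match")
    rows = []
    for sv_col in sv_proportions.columns:
        for acc_col in class_accuracies.columns:
            rho, p = spearman_corr(
                sv_proportions[sv_col].to_numpy(),
                class_accuracies[acc_col].to_numpy(),
            )
            rows.append(
                {
                    "sv_measure": sv_col,
                    "class": acc_col,
                    "rho": rho,
                    "p": p,
                    "sign": int(np.sign(rho)),
                }
            )
    return pd.DataFrame(rows)


def compare_procedures(
    balanced: pd.DataFrame, family_size: int | None = None
) -> dict:
    """Omnibus Friedman plus all pairwise Wilcoxon tests on a subjects x
    procedures balanced-accuracy table (Bonferroni family = number of pairs)."""
    cols = list(balanced.columns)
    n_pairs = len(cols) * (len(cols) - 1) // 2
    family = n_pairs if family_size is None else family_size
    stat, p = friedman_test(balanced.to_numpy())
    pairwise = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            w, raw, adj = wilcoxon_paired(
                balanced[cols[i]].to_numpy(),
                balanced[cols[j]].to_numpy(),
                correction_family_size=family,
            )
            better = cols[i] if balanced[cols[i]].median() >= balanced[cols[j]].median() else cols[j]
            pairwise.append(
                {
                    "a": cols[i],
                    "b": cols[j],
                    "statistic": w,
                    "p_raw": raw,
                    "p_bonferroni": adj,
                    "higher_median": better,
                }
            )
    return {
        "friedman_statistic": stat,
        "friedman_p": p,
        "pairwise": pd.DataFrame(pairwise),
    }
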