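"""Cohort-level differential feature analysis.

Per-feature two-sided Wilcoxon rank-sum tests with Benjamini-Hochberg
(default) or Bonferroni multiple-testing correction, log2 fold changes,
hyper/hypo direction calls and two-sample Kolmogorov-Smirnov distribution
shift testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: floor applied to group means of positive-valued features before log2
PSEUDO_MEAN_FLOOR = 1e-6


@dataclass
class DifferentialResult:
    """Per-feature comparison of a case cohort against a control cohort.

    ``table`` columns: feature, log2_fc, p, p_adj, direction
    (``up``/``down``/``unchanged``).  ``log_fc_flagged`` lists features
    where a mean difference replaced the log fold change (non-positive
    values present).
    """

    table: pd.DataFrame
    alpha: float = 0.05
    method: str = "bh"
    log_fc_flagged: list[str] = field(default_factory=list)


def wilcoxon_bh(
    matrix: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    method: str = "bh",
) -> DifferentialResult:
    """Rank-sum test per feature with multiple-testing correction.

    ``labels`` is binary (1 = case/cancer, 0 = control).  The log2 fold
    change is ``log2(mean_case / mean_control)`` for features that are
    strictly positive in both groups on average (with a 1e-6 floor);
    features with non-positive values fall back to the mean difference and
    are flagged.
    """
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    X = matrix.to_numpy(dtype=float)
    case, ctrl = X[y == 1], X[y == 0]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per group")

    # two-sided Mann-Whitney / Wilcoxon rank-sum per feature; exact null
    # distribution at small n without ties, normal approximation otherwise
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method="auto", axis=0)
    p = np.atleast_1d(res.pvalue)

    mean_case, mean_ctrl = np.nanmean(case, axis=0), np.nanmean(ctrl, axis=0)
    positive = (np.nanmin(X, axis=0) >= 0) & (mean_case + mean_ctrl > 0)
    with np.errstate(divide="ignore"):
        log_fc = np.where(
            positive,
            np.log2(np.maximum(mean_case, PSEUDO_MEAN_FLOOR)
                    / np.maximum(mean_ctrl, PSEUDO_MEAN_FLOOR)),
            mean_case - mean_ctrl,
        )
    flagged = matrix.columns[~positive].tolist()

    if method == "bh":
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    elif method == "bonferroni":
        _, p_adj, _, _ = multipletests(p, method="bonferroni")
    else:
        raise ValueError(f"unknown correction method {method!r}")

    direction = np.where(
        (p_adj <= alpha) & (log_fc > 0), "up",
        np.where((p_adj <= alpha) & (log_fc < 0), "down", "unchanged"),
    )
    table = pd.DataFrame(
        {
            "feature": matrix.columns,
            "log2_fc": log_fc,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    )
    return DifferentialResult(table=table, alpha=alpha, method=method,
                              log_fc_flagged=flagged)


def classify_bins(result: DifferentialResult) -> dict[str, int]:
    """Counts of hyper (up), hypo (down) and unchanged features."""
    counts = result.table["direction"].value_counts()
    return {
        "hyper": int(counts.get("up", 0)),
        "hypo": int(counts.get("down", 0)),
        "unchanged": int(counts.get("unchanged", 0)),
    }


def ks_shift_test(values_a, values_b) -> float:
    """Two-sample Kolmogorov-Smirnov p-value for a distribution shift."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b).pvalue)


def volcano_table(result: DifferentialResult) -> pd.DataFrame:
    """Feature, log2 fold change and -log10 adjusted p, for volcano plots."""
    t = result.table
    with np.errstate(divide="ignore"):
        neg_log = -np.log10(np.maximum(t["p_adj"].to_numpy(), np.finfo(float).tiny))
    return pd.DataFrame(
        {"feature": t["feature"], "log2_fc": t["log2_fc"], "neg_log10_p_adj": neg_log}
    )
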