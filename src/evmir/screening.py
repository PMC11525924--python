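"""Per-species differential screening: Mann-Whitney U tests, fold changes,
volcano filtering, significance counts and detection-prevalence summaries.

Design notes
------------
* The U statistic counts (x_i, y_j) pairs with x_i > y_j plus half the tied
  pairs. When both groups have <= 8 observations and there are no ties the
  two-sided p-value is exact — computed from the integer rank-sum
  distribution (dynamic programming over subset sums), so it agrees bit-for-
  bit with brute-force enumeration of all group assignments. Otherwise the
  normal approximation with tie and continuity corrections is used
  (delegated to scipy).
* Fold change is the log2 ratio of *linear-scale* normalized group means;
  the rank test is run on log2 values with undetected entries at the floor,
  so prevalence differences contribute to significance. The ranks are the
  same on either scale, so p-values are scale-invariant.
* Volcano thresholds are strict: -log10(p) > 3.30 and |log2 FC| > 1.00 by
  default.
"""

from __future__ import annotations

from math import comb
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .matrix import IntensityMatrix, CohortLabels, align

EXACT_MAX_N = 8
DEFAULT_NEGLOG10P_MIN = 3.30
DEFAULT_ABS_LFC_MIN = 1.00
DEFAULT_P_THRESHOLDS = (0.05, 0.005, 0.0005)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x via midranks: #pairs x>y + half the tied pairs."""
    n1 = x.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p via the integer distribution of U under H0 (no ties).

    Counts subsets of size n1 from ranks 1..n1+n2 by rank sum (DP with
    Python ints), then sums the two symmetric tails:
    p = P(|U' - n1*n2/2| >= |u - n1*n2/2|).
    """
    N = n1 + n2
    max_sum = N * (N + 1) // 2
    # dp[k][s] = number of k-subsets of {1..N} with sum s
    dp = [[0] * (max_sum + 1) for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            row_k, row_km1 = dp[k], dp[k - 1]
            for s in range(max_sum, r - 1, -1):
                if row_km1[s - r]:
                    row_k[s] += row_km1[s - r]
    offset = n1 * (n1 + 1) // 2          # U = ranksum - offset
    total = comb(N, n1)
    # work in doubled units so half-integer distances stay exact
    d_obs = abs(round(2 * u) - n1 * n2)
    count = 0
    for s in range(offset, max_sum + 1):
        if dp[n1][s] and abs(2 * (s - offset) - n1 * n2) >= d_obs:
            count += dp[n1][s]
    return count / total


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic for ``x``. Exact enumeration
    when both groups have <= 8 values and no ties; normal approximation with
    tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    u = _u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(u, x.size, y.size)
    else:
        if np.unique(combined).size == 1:
            return u, 1.0               # all values identical: no evidence
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(min(res.pvalue, 1.0))
    return u, p


def log2_fold_change(cancer_values, noncancer_values) -> float:
    """log2(mean cancer / mean noncancer) on the linear normalized scale.

    Returns NaN (undefined-fold-change sentinel) when either group mean is
    zero; such species are excluded from the volcano but kept in the table.
    """
    mc = float(np.mean(cancer_values))
    mn = float(np.mean(noncancer_values))
    if mc <= 0.0 or mn <= 0.0:
        return float("nan")
    return float(np.log2(mc / mn))


def screen_cohort(normalized: IntensityMatrix, labels: CohortLabels,
                  floor: float = 1.0,
                  neglog10p_min: float = DEFAULT_NEGLOG10P_MIN,
                  abs_lfc_min: float = DEFAULT_ABS_LFC_MIN,
                  include_undetected: bool = True) -> pd.DataFrame:
    """Per-species statistics table for a normalized (linear-scale) cohort.

    Columns: ``mean_log2_cancer``, ``mean_log2_noncancer``, ``U``, ``p``,
    ``log2_fc``, ``prevalence``, ``direction`` (up/down/ns per the volcano
    thresholds). Undetected entries enter the rank test at the floor value
    unless ``include_undetected`` is False (then they are dropped per
    species and group).
    """
    normalized.require_state("normalized")
    align(normalized, labels)
    vals = normalized.values.to_numpy(dtype=float)
    mask = normalized.mask.to_numpy()
    is_ca = labels.is_cancer.reindex(normalized.sample_ids).to_numpy()
    if is_ca.all() or not is_ca.any():
        raise InvalidInputError("both cancer and noncancer samples are required")

    log2_vals = np.log2(np.maximum(vals, floor))
    Xc, Xn = log2_vals[:, is_ca], log2_vals[:, ~is_ca]
    n1, n2 = Xc.shape[1], Xn.shape[1]

    if include_undetected and (n1 > EXACT_MAX_N or n2 > EXACT_MAX_N):
        # vectorized asymptotic test across all species at once
        res = stats.mannwhitneyu(Xc, Xn, alternative="two-sided",
                                 method="asymptotic", axis=1)
        U = np.asarray(res.statistic, dtype=float)
        pvals = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
        # constant rows: scipy emits nan (zero variance); no evidence -> p=1
        const = (log2_vals.max(axis=1) == log2_vals.min(axis=1))
        pvals[const] = 1.0
        U[const] = n1 * n2 / 2.0
    else:
        U = np.empty(vals.shape[0])
        pvals = np.empty(vals.shape[0])
        for i in range(vals.shape[0]):
            xi, yi = Xc[i], Xn[i]
            if not include_undetected:
                xi = xi[mask[i, is_ca]]
                yi = yi[mask[i, ~is_ca]]
            U[i], pvals[i] = mann_whitney_u(xi, yi)

    lin_c, lin_n = vals[:, is_ca], vals[:, ~is_ca]
    mean_c, mean_n = lin_c.mean(axis=1), lin_n.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where((mean_c > 0) & (mean_n > 0),
                       np.log2(np.where(mean_c > 0, mean_c, 1.0)
                               / np.where(mean_n > 0, mean_n, 1.0)),
                       np.nan)
    featured = (-np.log10(np.maximum(pvals, 1e-300)) > neglog10p_min) \
        & (np.abs(lfc) > abs_lfc_min) & ~np.isnan(lfc)
    direction = np.where(featured & (lfc > 0), "up",
                         np.where(featured & (lfc < 0), "down", "ns"))

    return pd.DataFrame({
        "mean_log2_cancer": Xc.mean(axis=1),
        "mean_log2_noncancer": Xn.mean(axis=1),
        "U": U,
        "p": pvals,
        "log2_fc": lfc,
        "prevalence": mask.mean(axis=1),
        "direction": direction,
    }, index=normalized.probe_ids)


def volcano_filter(stats_table: pd.DataFrame,
                   neglog10p_min: float = DEFAULT_NEGLOG10P_MIN,
                   abs_lfc_min: float = DEFAULT_ABS_LFC_MIN) -> pd.DataFrame:
    """Species with -log10(p) > ``neglog10p_min`` and |log2 FC| >
    ``abs_lfc_min`` (both strict), tagged up/down by fold-change sign.
    Species with an undefined fold change are excluded."""
    p = stats_table["p"].to_numpy(dtype=float)
    lfc = stats_table["log2_fc"].to_numpy(dtype=float)
    keep = (-np.log10(np.maximum(p, 1e-300)) > neglog10p_min) \
        & (np.abs(lfc) > abs_lfc_min) & ~np.isnan(lfc)
    out = stats_table.loc[keep].copy()
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out


def significance_counts(stats_table: pd.DataFrame,
                        thresholds=DEFAULT_P_THRESHOLDS) -> dict[float, int]:
    """Number of species with p < t for each threshold t (strictly
    decreasing threshold list required)."""
    thr = list(thresholds)
    if any(b >= a for a, b in zip(thr, thr[1:])):
        raise InvalidInputError("thresholds must be strictly decreasing")
    p = stats_table["p"].to_numpy(dtype=float)
    return {t: int((p < t).sum()) for t in thr}


@dataclass
class PrevalenceSummary:
    n_detected_any: int
    n_detected_all: int
    per_subject_counts: pd.Series


def prevalence_summary(m: IntensityMatrix) -> PrevalenceSummary:
    """Species detected in >= 1 sample, in all samples, and per-subject
    detected-species counts (the box-plot summary)."""
    mask = m.mask.to_numpy()
    return PrevalenceSummary(
        n_detected_any=int(mask.any(axis=1).sum()),
        n_detected_all=int(mask.all(axis=1).sum()),
        per_subject_counts=pd.Series(mask.sum(axis=0), index=m.sample_ids,
                                     name="n_detected"),
    )
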