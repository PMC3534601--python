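"""Per-probe sex-difference screening within one tissue.

The primary screen is the two-sided Wilcoxon (Mann-Whitney) rank-sum test in
its normal approximation: midranks for ties, tie-corrected variance and a 0.5
continuity correction — the convention of standard statistical environments.
A Welch two-sample t-test is computed alongside as the parametric companion.
No multiple-testing adjustment is applied at any point: probes are called
female- or male-biased by comparing the unadjusted rank-sum p-value with the
chosen threshold (0.001 for the primary screen, 0.01 for the relaxed
multi-tissue screen).

Fold-changes are reported as ``delta`` = mean(female) - mean(male) on the
log2 scale and ``fold_change`` = 2**delta on the linear female/male scale.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError, MetadataError
from .model import FEMALE, MALE, ExpressionMatrix, SampleTable

#: Bias-call labels.
NS = "ns"

RESULT_COLUMNS = (
    "mean_f",
    "mean_m",
    "delta",
    "fold_change",
    "p_wilcoxon",
    "p_ttest",
    "call",
)


def _tie_term(sorted_rows: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per row of a sorted 2-D array."""
    n_rows, n = sorted_rows.shape
    out = np.zeros(n_rows)
    tied = sorted_rows[:, 1:] == sorted_rows[:, :-1]
    rows_with_ties = np.flatnonzero(tied.any(axis=1))
    for i in rows_with_ties:
        row = sorted_rows[i]
        _, counts = np.unique(row, return_counts=True)
        counts = counts[counts > 1].astype(float)
        out[i] = float((counts**3 - counts).sum())
    return out


def rank_sum_p_matrix(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p (normal approximation).

    ``xs`` and ``ys`` are 2-D arrays (probes x samples) sharing the first
    axis. Midranks handle ties; the rank variance is tie-corrected; a 0.5
    continuity correction is applied toward the null mean. Rows where every
    value is tied get p = 1.
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    ys = np.atleast_2d(np.asarray(ys, dtype=float))
    n1, n2 = xs.shape[1], ys.shape[1]
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    pooled = np.concatenate([xs, ys], axis=1)
    n = n1 + n2
    ranks = sps.rankdata(pooled, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = _tie_term(np.sort(pooled, axis=1))
    sigma2 = (n1 * n2 / 12.0) * ((n + 1.0) - tie / (n * (n - 1.0)))
    centered = u - mu
    corrected = centered - 0.5 * np.sign(centered)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = corrected / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(sigma2 <= 0.0, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def rank_sum_p(xs, ys) -> float:
    """Two-sided rank-sum p for a single pair of samples."""
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    return float(rank_sum_p_matrix(xs[None, :], ys[None, :])[0])


def t_test_p_matrix(xs: np.ndarray, ys: np.ndarray, equal_var: bool = False) -> np.ndarray:
    """Row-wise two-sided t-test p (Welch by default).

    Rows with zero variance in both groups get p = 1 when the group means are
    equal and p = 0 when they differ (complete separation of constants).
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    ys = np.atleast_2d(np.asarray(ys, dtype=float))
    if xs.shape[1] < 2 or ys.shape[1] < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(xs, ys, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    var_x = xs.var(axis=1, ddof=1)
    var_y = ys.var(axis=1, ddof=1)
    degenerate = (var_x == 0.0) & (var_y == 0.0)
    if degenerate.any():
        same = np.isclose(xs.mean(axis=1), ys.mean(axis=1))
        p = np.where(degenerate & same, 1.0, p)
        p = np.where(degenerate & ~same, 0.0, p)
    return np.clip(p, 0.0, 1.0)


def t_test_p(xs, ys, equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p for a single pair of samples.

    Zero variance in both groups with equal means returns 1 by convention;
    zero variance with different means is a degenerate input.
    """
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    if xs.var(ddof=1) == 0.0 and ys.var(ddof=1) == 0.0:
        if np.isclose(xs.mean(), ys.mean()):
            return 1.0
        raise DegenerateInputError("zero variance in both groups with unequal means")
    return float(t_test_p_matrix(xs[None, :], ys[None, :], equal_var=equal_var)[0])


def fold_change(xs, ys) -> tuple[float, float]:
    """(delta, fold_change): log2 mean difference and its linear-scale ratio."""
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise InsufficientDataError("fold change needs non-empty groups")
    delta = float(xs.mean() - ys.mean())
    return delta, float(2.0**delta)


def test_tissue(
    m: ExpressionMatrix, samples: SampleTable, alpha: float = 0.001
) -> pd.DataFrame:
    """Screen every probe of one tissue for sex-biased expression.

    Returns a DataFrame indexed by probe_id with columns mean_f, mean_m,
    delta, fold_change, p_wilcoxon, p_ttest and call. The call is ``female``
    if p_wilcoxon < alpha and delta > 0, ``male`` if p_wilcoxon < alpha and
    delta < 0, otherwise ``ns`` (including the measure-zero delta == 0 case,
    where the direction is undefined).
    """
    sex = samples.sex_of(m.sample_ids)
    f_cols = [s for s, sx in zip(m.sample_ids, sex) if sx == FEMALE]
    m_cols = [s for s, sx in zip(m.sample_ids, sex) if sx == MALE]
    if len(f_cols) < 2 or len(m_cols) < 2:
        raise InsufficientDataError(
            f"need >=2 samples per sex; found {len(f_cols)} female, {len(m_cols)} male"
        )
    fvals = m.data[f_cols].to_numpy()
    mvals = m.data[m_cols].to_numpy()
    mean_f = fvals.mean(axis=1)
    mean_m = mvals.mean(axis=1)
    delta = mean_f - mean_m
    p_w = rank_sum_p_matrix(fvals, mvals)
    p_t = t_test_p_matrix(fvals, mvals)
    call = np.full(len(delta), NS, dtype=object)
    call[(p_w < alpha) & (delta > 0)] = FEMALE
    call[(p_w < alpha) & (delta < 0)] = MALE
    return pd.DataFrame(
        {
            "mean_f": mean_f,
            "mean_m": mean_m,
            "delta": delta,
            "fold_change": 2.0**delta,
            "p_wilcoxon": p_w,
            "p_ttest": p_t,
            "call": call,
        },
        index=pd.Index(m.probe_ids, name="probe_id"),
    )


def recall_at(results: pd.DataFrame, alpha: float) -> pd.Series:
    """Re-derive bias calls from stored p-values at a different threshold."""
    call = np.full(len(results), NS, dtype=object)
    sig = results["p_wilcoxon"] < alpha
    call[sig & (results["delta"] > 0)] = FEMALE
    call[sig & (results["delta"] < 0)] = MALE
    return pd.Series(call, index=results.index, name="call")


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-probe result table (tab-delimited)."""
    results.to_csv(path, sep="\t", float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    """Read a per-probe result table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"result table missing columns {sorted(missing)}")
    return df
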