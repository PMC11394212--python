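"""Cohort-level statistics: paired Wilcoxon comparison of per-experiment
CD32 medians, Pearson agreement between automated and manual readouts,
and Tukey-style outlier flagging of auto-vs-manual differences.

The Wilcoxon matched-pairs signed-rank test discards zero differences
(the classic convention; the equal pairs are reported separately), uses
midranks for ties, and switches between an exact distribution (n <= 12,
dynamic programming over doubled ranks) and the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

EXACT_N_MAX = 12


class WilcoxonResult(NamedTuple):
    z_statistic: float
    p_value: float  # two-tailed
    n_used: int     # non-zero-difference pairs
    n_higher: int   # first member of the pair higher
    n_lower: int
    n_equal: int
    method: str     # "exact" | "asymptotic" | "degenerate"


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        a = pairs.iloc[:, 0].to_numpy(dtype=float)
        b = pairs.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) table")
        a, b = arr[:, 0], arr[:, 1]
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("pairs must be complete (no missing medians)")
    return a, b


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact null distribution of W+ by DP over doubled (integer) ranks."""
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in doubled:
        counts[r : top + r + 1] += counts[: top + 1]
        top += r
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_matched_pairs(pairs) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test on (first - second) pairs."""
    a, b = _as_pairs(pairs)
    d = a - b
    n_higher = int(np.count_nonzero(d > 0))
    n_lower = int(np.count_nonzero(d < 0))
    n_equal = int(np.count_nonzero(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_higher, n_lower, n_equal, "degenerate")

    ranks = stats.rankdata(np.abs(d))  # midranks on |d|
    w_plus = float(ranks[d > 0].sum())

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(0.0, 1.0, n, n_higher, n_lower, n_equal, "degenerate")
    cc = 0.5 * np.sign(w_plus - mu)  # continuity correction toward the mean
    z = (w_plus - mu - cc) / np.sqrt(var)

    if n <= EXACT_N_MAX:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "asymptotic"
    return WilcoxonResult(float(z), p, n, n_higher, n_lower, n_equal, method)


class PearsonResult(NamedTuple):
    r: float
    r_squared: float
    p_value: float


def pearson_r(a: Sequence[float], b: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with a t-distribution p value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("pearson_r needs two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    res = stats.pearsonr(a, b)
    r = float(res.statistic)
    return PearsonResult(r, r * r, float(res.pvalue))


def nearest_rank_quartiles(values: np.ndarray) -> tuple[float, float]:
    """(Q1, Q3) with the nearest-rank convention (k = ceil(q * n))."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    k1 = max(1, int(np.ceil(0.25 * n)))
    k3 = max(1, int(np.ceil(0.75 * n)))
    return float(v[k1 - 1]), float(v[k3 - 1])


def flag_outliers(diffs: Sequence[float]) -> np.ndarray:
    """Boolean mask: |difference| greater than Q3 + 1.5 * IQR of the
    absolute differences (nearest-rank quartiles)."""
    d = np.abs(np.asarray(diffs, dtype=float))
    if len(d) < 4:
        raise ValueError("outlier flagging needs at least 4 values")
    q1, q3 = nearest_rank_quartiles(d)
    threshold = q3 + 1.5 * (q3 - q1)
    return d > threshold


def agreement_table(auto: Sequence[float], manual: Sequence[float]) -> pd.DataFrame:
    """Per-sample auto vs manual CD63+ frequencies with outlier flags."""
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if len(auto) != len(manual):
        raise ValueError("auto and manual vectors must align")
    diff = auto - manual
    return pd.DataFrame({
        "auto": auto, "manual": manual, "difference": diff,
        "outlier": flag_outliers(diff),
    })


class ExperimentClassification(NamedTuple):
    higher: int  # non-allergic median above allergic
    lower: int
    equal: int


def classify_experiments(pairs) -> ExperimentClassification:
    """Tally the per-experiment sign of (non-allergic - allergic) medians."""
    a, b = _as_pairs(pairs)
    d = a - b
    return ExperimentClassification(
        higher=int(np.count_nonzero(d > 0)),
        lower=int(np.count_nonzero(d < 0)),
        equal=int(np.count_nonzero(d == 0)),
    )
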