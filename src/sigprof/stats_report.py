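"""Population-level statistics: half-life CDFs, condition comparisons,
stress-signaling correlation, kinetic-parameter density summaries, and a
dip test of unimodality.

The dip statistic here is the minimum over all unimodal distribution
functions U of sup_x |F_n(x) - U(x)|, where F_n is the sample's empirical
CDF.  A unimodal CDF is convex up to its mode and concave after it, with at
most one atom, located at the mode.  The statistic is computed exactly (to
binary-search precision) by finding the smallest band half-width eps for
which a convex-then-concave CDF fits inside [F_n - eps, F_n + eps]; the
p-value is Monte Carlo under the uniform null, the standard calibration for
this test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("sigprof")

__all__ = [
    "CdfCurve",
    "TTestResult",
    "CorrelationResult",
    "DensitySummary",
    "ecdf",
    "compare_conditions",
    "compare_cdfs_ks",
    "stress_signal_correlation",
    "amplitude_rate_densities",
    "dip_statistic",
    "dip_test",
]


# ---------------------------------------------------------------------------
# empirical CDFs
# ---------------------------------------------------------------------------

@dataclass
class CdfCurve:
    """Right-continuous empirical CDF of one condition's values."""

    values: np.ndarray  # sorted
    probs: np.ndarray  # i/n at each sorted value
    condition: Optional[str] = None
    n: int = 0

    def evaluate(self, q) -> np.ndarray:
        """Fraction of sample values <= q (vectorized)."""
        q = np.asarray(q, dtype=float)
        return np.searchsorted(self.values, q, side="right") / self.n

    def quantile(self, p) -> np.ndarray:
        return np.quantile(self.values, p, method="inverted_cdf")


def ecdf(values, condition: Optional[str] = None) -> CdfCurve:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    srt = np.sort(values)
    n = srt.size
    return CdfCurve(values=srt, probs=np.arange(1, n + 1) / n, condition=condition, n=n)


# ---------------------------------------------------------------------------
# condition comparison (two-tailed pooled-variance t-test on well summaries)
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def compare_conditions(a, b) -> TTestResult:
    """Two-tailed equal-variance (pooled) t-test between two groups.

    Intended for well-level summaries (N = wells), not per-cell values.
    Zero pooled variance with equal means yields t = 0, p = 1 by convention;
    zero pooled variance with different means is flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, df=df)
        return TTestResult(t=np.inf if a.mean() > b.mean() else -np.inf, p=0.0, df=df, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), p=float(p), df=df)


def compare_cdfs_ks(a, b) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of half-life distributions.

    Offered as an extension: the primary CDF readout is descriptive.
    """
    res = sps.ks_2samp(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# stress vs Ca2+ signaling correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    slope: float
    intercept: float
    weak: bool = False  # |r| < 0.1


def stress_signal_correlation(
    table: pd.DataFrame,
    stress_col: str = "stress_score",
    signal_col: str = "max_dff",
) -> CorrelationResult:
    """Pearson correlation (and least-squares line) between per-cell stress
    scores and the maximum Ca²⁺ fold change."""
    x = np.asarray(table[stress_col], dtype=float)
    y = np.asarray(table[signal_col], dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 cells")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    lin = sps.linregress(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), n=x.size,
        slope=float(lin.slope), intercept=float(lin.intercept),
        weak=bool(abs(r) < 0.1),
    )


# ---------------------------------------------------------------------------
# kinetic-parameter distributions
# ---------------------------------------------------------------------------

@dataclass
class DensitySummary:
    """Per-condition summary of one fitted parameter's distribution."""

    condition: str
    parameter: str
    n: int
    quantiles: Dict[float, float]
    grid: np.ndarray
    density: np.ndarray
    dip: float
    dip_p: float


_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def amplitude_rate_densities(
    fits: pd.DataFrame,
    by: str = "condition",
    parameters: Sequence[str] = ("alpha", "theta"),
    min_fits: int = 10,
    n_grid: int = 256,
    dip_boot: int = 100,
) -> list:
    """Kernel-density summaries (Silverman bandwidth) and quantiles of fitted
    parameters per condition, with a dip-test unimodality report.

    Only converged fits enter; a condition with fewer than ``min_fits`` of
    them is an error.
    """
    if "converged" in fits.columns:
        fits = fits[fits["converged"].astype(bool)]
    out = []
    for cond, sub in fits.groupby(by, sort=True):
        for param in parameters:
            vals = np.asarray(sub[param].dropna(), dtype=float)
            if vals.size < min_fits:
                raise ValueError(
                    f"condition {cond!r} has {vals.size} converged fits for "
                    f"{param!r}; need >= {min_fits}"
                )
            pad = 0.1 * np.ptp(vals) if np.ptp(vals) > 0 else 1.0
            grid = np.linspace(vals.min() - pad, vals.max() + pad, n_grid)
            if np.ptp(vals) > 0:
                kde = sps.gaussian_kde(vals, bw_method="silverman")
            else:
                kde = lambda g: np.zeros_like(g)  # degenerate: all mass at one point
            dip, dip_p = dip_test(vals, n_boot=dip_boot)
            out.append(
                DensitySummary(
                    condition=str(cond),
                    parameter=param,
                    n=vals.size,
                    quantiles={q: float(np.quantile(vals, q)) for q in _QUANTILES},
                    grid=grid,
                    density=kde(grid),
                    dip=dip,
                    dip_p=dip_p,
                )
            )
    return out


# ---------------------------------------------------------------------------
# dip statistic of unimodality
# ---------------------------------------------------------------------------

def _group_boxes(xs: np.ndarray, los: np.ndarray, his: np.ndarray):
    """Merge duplicate x positions: lower bounds take the max, caps the min."""
    if xs.size <= 1:
        return xs, los, his
    change = np.flatnonzero(np.diff(xs) > 0)
    starts = np.concatenate(([0], change + 1))
    return (
        xs[starts],
        np.maximum.reduceat(los, starts),
        np.minimum.reduceat(his, starts),
    )


def _convex_fits(xs: np.ndarray, los: np.ndarray, his: np.ndarray) -> bool:
    """Does a convex nondecreasing function (rising from 0 left of the data)
    pass through every box [los_i, his_i] at xs_i?  Assumes caps
    nondecreasing in i (true for ecdf bands).  Feasible iff the greatest
    convex minorant of the caps clears every lower bound."""
    xs, los, his = _group_boxes(xs, los, his)
    if np.any(los > his + 1e-12):
        return False
    m = xs.size
    if m <= 2:
        return True
    hx: list = []
    hy: list = []
    for x, h in zip(xs, his):
        while len(hx) >= 2 and (
            (hx[-1] - hx[-2]) * (h - hy[-2]) - (hy[-1] - hy[-2]) * (x - hx[-2]) <= 0.0
        ):
            hx.pop()
            hy.pop()
        hx.append(x)
        hy.append(h)
    vals = np.interp(xs, hx, hy)
    return bool(np.all(vals >= los - 1e-12))


def _concave_fits(xs: np.ndarray, los: np.ndarray, his: np.ndarray) -> bool:
    """Concave nondecreasing branch (rising to 1 right of the data) through
    the boxes; mirror image of the convex case via V(y) = 1 - U(-y)."""
    return _convex_fits(-xs[::-1], (1.0 - his)[::-1], (1.0 - los)[::-1])


def _max_true_prefix(pred, lo: int, hi: int) -> int:
    """Largest m in [lo, hi] with pred(m) True, assuming pred is monotone
    nonincreasing in m; returns lo - 1 when even pred(lo) is False."""
    if not pred(lo):
        return lo - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if pred(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _band_feasible(xs: np.ndarray, lo_arr: np.ndarray, hi_arr: np.ndarray, eps: float) -> bool:
    """Is there a unimodal CDF inside the band [ecdf - eps, ecdf + eps]?

    Splits the sample at a mode either strictly between data points (indices
    0..s convex, s+1.. concave) or exactly at a data point, whose atom
    absorbs the ecdf jump there.  Each branch feasibility is monotone in the
    split index, so the split is located by binary search.
    """
    n = xs.size
    los = np.maximum(lo_arr - eps, 0.0)
    his = np.minimum(hi_arr + eps, 1.0)

    # mode strictly between data points (or outside the data range)
    pre = _max_true_prefix(
        lambda m: _convex_fits(xs[:m], los[:m], his[:m]), 0, n
    )  # longest feasible convex prefix length
    suf = _max_true_prefix(
        lambda m: _concave_fits(xs[n - m:], los[n - m:], his[n - m:]), 0, n
    )  # longest feasible concave suffix length
    if pre + suf >= n:
        return True

    # mode at data point x_j: the left branch sees only the left-limit cap at
    # x_j; the right branch's first box is relaxed to the post-jump value.
    def prefix_cap(j: int) -> bool:
        if j == 0:
            return True
        xs_l = xs[: j + 1]
        los_l = np.concatenate((los[:j], [0.0]))
        his_l = np.concatenate((his[:j], [min(hi_arr[j] + eps, 1.0)]))
        return _convex_fits(xs_l, los_l, his_l)

    def suffix_relaxed(j: int) -> bool:
        his_r = his[j:].copy()
        his_r[0] = min(lo_arr[j] + eps, 1.0)  # (j+1)/n + eps
        return _concave_fits(xs[j:], los[j:], his_r)

    j_left = _max_true_prefix(prefix_cap, 0, n - 1)
    if j_left < 0:
        return False
    # suffix_relaxed is monotone nondecreasing in j: find smallest feasible j
    lo_j, hi_j = 0, n - 1
    if not suffix_relaxed(hi_j):
        return False
    while lo_j < hi_j:
        mid = (lo_j + hi_j) // 2
        if suffix_relaxed(mid):
            hi_j = mid
        else:
            lo_j = mid + 1
    return lo_j <= j_left


def dip_statistic(x) -> float:
    """Hartigan dip statistic: sup-norm distance from the empirical CDF to
    the nearest unimodal CDF.  0 for constant samples; at least 1/(2n) for
    samples with >= 2 distinct values; at most 0.25."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if n == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(xs)):
        raise ValueError("values must be finite")
    if n == 1 or xs[0] == xs[-1]:
        return 0.0
    lo_arr = np.arange(1, n + 1) / n  # ecdf value at x_i (right-continuous)
    hi_arr = np.arange(0, n) / n  # ecdf left limit at x_i
    lo_eps, hi_eps = 0.0, 0.5
    for _ in range(42):
        mid = 0.5 * (lo_eps + hi_eps)
        if _band_feasible(xs, lo_arr, hi_arr, mid):
            hi_eps = mid
        else:
            lo_eps = mid
    return 0.5 * (lo_eps + hi_eps)


@lru_cache(maxsize=32)
def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])


def dip_test(x, n_boot: int = 100, seed: int = 1234) -> Tuple[float, float]:
    """Dip test of unimodality.

    Returns (dip, p); p is Monte Carlo against ``n_boot`` uniform null
    samples of the same size (null draws are cached per sample size).  Small
    p rejects unimodality (bi-/multi-modal sample).
    """
    x = np.asarray(x, dtype=float)
    d = dip_statistic(x)
    null = _null_dips(int(x.size), int(n_boot), int(seed))
    p = (1.0 + float(np.sum(null >= d))) / (1.0 + null.size)
    return d, p
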