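"""Dip statistic vs an independent linear-programming oracle.

The oracle solves the defining minimization directly: over every mode
placement (strictly between data points, or at a data point, where the
unimodal CDF may carry its single atom), find by LP the smallest band
half-width eps admitting a convex-then-concave nondecreasing CDF through
the eps-band around the empirical CDF.  Convexity/concavity are linear
constraints on the CDF values at the data points, with far anchor knots
pinning the tails at 0 and 1.
"""

import numpy as np
import pytest
from scipy.optimize import linprog

from sigprof.stats_report import dip_statistic, dip_test


def _branch_rows(xs, n_var, offset, anchor, concave):
    """Convexity (or concavity) + monotonicity rows for one branch."""
    A, b = [], []
    m = len(xs)
    for k in range(m - 1):  # monotone nondecreasing
        row = np.zeros(n_var)
        row[offset + k] = 1.0
        row[offset + k + 1] = -1.0
        A.append(row)
        b.append(0.0)
    # slopes of consecutive segments, including the anchor segment
    pts = ([anchor] + list(xs)) if not concave else (list(xs) + [anchor])
    segs = []
    for k in range(len(pts) - 1):
        dx = pts[k + 1] - pts[k]
        segs.append((k, dx))
    for (k1, dx1), (k2, dx2) in zip(segs, segs[1:]):
        # slope_k1 <= slope_k2 (convex); reversed for concave
        row = np.zeros(n_var)
        const = 0.0

        def add(node_idx, coef):
            nonlocal const
            # node 0 in pts is the anchor for convex; last is anchor for concave
            if not concave and node_idx == 0:
                const += coef * 0.0
            elif concave and node_idx == len(pts) - 1:
                const += coef * 1.0
            else:
                var = node_idx - (0 if concave else 1)
                row[offset + var] += coef

        # slope1 - slope2 <= 0 (convex) ; slope2 - slope1 <= 0 (concave)
        sgn = 1.0 if not concave else -1.0
        add(k1 + 1, sgn / dx1)
        add(k1, -sgn / dx1)
        add(k2 + 1, -sgn / dx2)
        add(k2, sgn / dx2)
        A.append(row)
        b.append(-const)
    return A, b


def _lp_for_placement(xs, lo, hi, left_idx, right_idx, cap_at=None, relax_first_right=False):
    n = xs.size
    big = 1e6 * (xs[-1] - xs[0] + 1.0)

    def uniq(idx, extra_x=None):
        vals = [xs[i] for i in idx]
        if extra_x is not None:
            vals.append(extra_x)
        out, mapping = [], []
        for v in vals:
            if not out or v > out[-1]:
                out.append(v)
            mapping.append(len(out) - 1)
        return out, mapping

    cap_x = xs[cap_at] if cap_at is not None else None
    xl, map_l = uniq(left_idx, cap_x)
    xr, map_r = uniq(right_idx)
    n_l, n_r = len(xl), len(xr)
    n_var = 1 + n_l + n_r  # eps, left values, right values
    A, b = [], []

    def box(var, lo_c=None, hi_c=None):
        if hi_c is not None:
            row = np.zeros(n_var)
            row[var] = 1.0
            row[0] = -1.0
            A.append(row)
            b.append(hi_c)
        if lo_c is not None:
            row = np.zeros(n_var)
            row[var] = -1.0
            row[0] = -1.0
            A.append(row)
            b.append(-lo_c)

    for pos, i in enumerate(left_idx):
        box(1 + map_l[pos], lo[i], hi[i])
    if cap_at is not None:
        box(1 + map_l[-1], None, hi[cap_at])
    for pos, i in enumerate(right_idx):
        if pos == 0 and relax_first_right:
            box(1 + n_l + map_r[pos], lo[i], lo[i])  # value within eps of (i+1)/n
        else:
            box(1 + n_l + map_r[pos], lo[i], hi[i])
    if n_l:
        rows, rhs = _branch_rows(xl, n_var, 1, xl[0] - big, concave=False)
        A += rows
        b += rhs
    if n_r:
        rows, rhs = _branch_rows(xr, n_var, 1 + n_l, xr[-1] + big, concave=True)
        A += rows
        b += rhs
    if n_l and n_r:  # junction: jump up only
        row = np.zeros(n_var)
        row[n_l] = 1.0
        row[1 + n_l] = -1.0
        A.append(row)
        b.append(0.0)
    bounds = [(0.0, 0.6)] + [(0.0, 1.0)] * (n_l + n_r)
    c = np.zeros(n_var)
    c[0] = 1.0
    res = linprog(c, A_ub=np.vstack(A) if A else None, b_ub=b or None, bounds=bounds, method="highs")
    return res.fun if res.status == 0 else np.inf


def lp_dip(x):
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    if n <= 1 or xs[0] == xs[-1]:
        return 0.0
    lo = np.arange(1, n + 1) / n
    hi = np.arange(0, n) / n
    best = np.inf
    for s in range(-1, n):  # mode strictly between points (or outside)
        best = min(best, _lp_for_placement(xs, lo, hi, list(range(s + 1)), list(range(s + 1, n))))
    for j in range(n):  # mode (atom) at data point j
        best = min(
            best,
            _lp_for_placement(
                xs, lo, hi, list(range(j)), list(range(j, n)),
                cap_at=j, relax_first_right=True,
            ),
        )
    return best


class TestDipClosedForms:
    def test_equally_spaced_sample_attains_lower_bound(self):
        for n in (2, 4, 7, 10):
            assert dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n), abs=1e-9)

    def test_two_balanced_atoms_attain_maximum(self):
        assert dip_statistic([0, 0, 0, 1, 1, 1]) == pytest.approx(0.25, abs=1e-9)

    def test_constant_sample_has_zero_dip(self):
        assert dip_statistic([5.0] * 8) == 0.0
        assert dip_statistic([5.0]) == 0.0


class TestDipAgainstLpOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_continuous_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        x = rng.normal(size=n)
        assert dip_statistic(x) == pytest.approx(lp_dip(x), abs=5e-6)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_samples_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 9))
        x = rng.integers(0, 4, size=n).astype(float)
        assert dip_statistic(x) == pytest.approx(lp_dip(x), abs=5e-6)

    def test_bimodal_beats_unimodal_dip(self):
        rng = np.random.default_rng(0)
        uni = rng.normal(size=200)
        bi = np.concatenate([rng.normal(-3, 0.3, 100), rng.normal(3, 0.3, 100)])
        assert dip_statistic(bi) > 3 * dip_statistic(uni)


class TestDipTest:
    def test_clear_bimodality_rejected_uniform_not(self):
        rng = np.random.default_rng(1)
        bi = np.concatenate([rng.normal(0, 0.05, 100), rng.normal(1, 0.05, 100)])
        _, p_bi = dip_test(bi)
        _, p_uni = dip_test(rng.uniform(size=200))
        assert p_bi < 0.05 <= p_uni
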