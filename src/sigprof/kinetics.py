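"""Per-cell kinetic models for biosensor traces.

Two models, fit by bounded least squares to stimulus-aligned ΔF/F traces:

* Ca²⁺ transient decay:  ΔF/F = α·e^(−θt), with amplitude α (unitless ΔF/F)
  and clearance rate θ (s⁻¹).
* cAMP degradation:      ΔF/F = α / (1 + β·e^(−θt)).  The biologically
  relevant branch is the decreasing sigmoid (θ < 0, β < 1), which decays from
  ≈α back toward baseline; its half-life is the closed form
  t½ = ln(β)/θ, the time at which the curve crosses α/2.

Fits that fail (no positive signal, no decay, optimizer failure, or a
half-life outside the observation window) are returned with
``converged=False`` and a reason, never with garbage parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .traces import Trace, TraceSet

log = logging.getLogger("sigprof")

__all__ = [
    "KineticFit",
    "LogisticFit",
    "fit_exponential",
    "fit_logistic",
    "half_life",
    "fit_traceset",
]

#: physical parameter envelope: amplitudes up to 10-fold ΔF/F,
#: rates between 1e-5 and 5 s⁻¹ in magnitude.
ALPHA_BOUNDS = (1e-9, 10.0)
THETA_MAX = 5.0
THETA_MIN = 1e-5
MAX_NFEV = 500
_TOL = 1e-12


@dataclass
class KineticFit:
    """Exponential-transient fit result (α·e^(−θt))."""

    alpha: float
    theta: float
    rss: float
    converged: bool
    n_points: int
    reason: Optional[str] = None


@dataclass
class LogisticFit:
    """Logistic-decay fit result (α / (1 + β·e^(−θt)))."""

    alpha: float
    beta: float
    theta: float
    t_half: float
    rss: float
    converged: bool
    n_points: int
    reason: Optional[str] = None


def _failed_exp(n, reason):
    return KineticFit(np.nan, np.nan, np.nan, False, n, reason)


def _failed_logistic(n, reason):
    return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, n, reason)


def _aligned_xy(trace: Trace):
    if trace.dff is None:
        raise ValueError("trace must be ΔF/F-normalized before fitting")
    t = trace.time - trace.time[0]
    return t, trace.dff


def fit_exponential(trace: Trace) -> KineticFit:
    """Least-squares fit of ΔF/F = α·e^(−θt) to an aligned trace.

    Initialization is deterministic and data-driven: α0 is the trace maximum,
    θ0 comes from an ordinary regression of ln(ΔF/F) on t over samples with
    ΔF/F > 0.05.
    """
    t, y = _aligned_xy(trace)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 samples to fit")
    peak = float(np.max(y))
    if peak <= 0:
        return _failed_exp(n, "no positive signal")
    a0 = float(np.clip(peak, 2e-9, ALPHA_BOUNDS[1]))
    pos = y > 0.05
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        th0 = float(np.clip(-slope, THETA_MIN, THETA_MAX))
    else:
        th0 = float(np.clip(1.0 / max(t[-1], 1.0), THETA_MIN, THETA_MAX))

    def resid(p):
        a, th = p
        return a * np.exp(-th * t) - y

    try:
        res = least_squares(
            resid,
            x0=[a0, th0],
            bounds=([ALPHA_BOUNDS[0], THETA_MIN], [ALPHA_BOUNDS[1], THETA_MAX]),
            ftol=_TOL, xtol=_TOL, gtol=_TOL, max_nfev=MAX_NFEV,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return _failed_exp(n, f"optimizer error: {exc}")
    if not res.success or not np.all(np.isfinite(res.x)):
        return _failed_exp(n, "optimizer did not converge")
    a, th = map(float, res.x)
    rss = float(np.sum(res.fun**2))
    return KineticFit(a, th, rss, True, n)


def fit_logistic(trace: Trace) -> LogisticFit:
    """Least-squares fit of ΔF/F = α / (1 + β·e^(−θt)) to an aligned decay.

    θ is left unconstrained in sign; accepted fits are decreasing over the
    window with a positive in-window half-life (the decaying branch: θ < 0,
    β < 1).  A trace whose terminal level stays at or above 90% of its peak
    is rejected up front as "no decay observed".  Internally β is optimized
    on a log scale for conditioning.
    """
    t, y = _aligned_xy(trace)
    n = t.size
    if n < 4:
        raise ValueError("need at least 4 samples to fit")
    peak = float(np.max(y))
    if peak <= 0:
        return _failed_logistic(n, "no positive signal")
    tail = y[-max(3, n // 10):]
    if float(np.mean(tail)) >= 0.9 * peak:
        return _failed_logistic(n, "no decay observed")

    a0 = float(np.clip(peak, 2e-9, ALPHA_BOUNDS[1]))
    # logit regression for (beta0, theta0): ln(a/y - 1) = ln(beta) - theta*t
    a_ref = 1.02 * a0
    sel = (y > 0.05 * a_ref) & (y < 0.95 * a_ref)
    if sel.sum() >= 2 and np.ptp(t[sel]) > 0:
        z = np.log(a_ref / y[sel] - 1.0)
        slope, intercept = np.polyfit(t[sel], z, 1)
        th0 = float(np.clip(-slope, -THETA_MAX, -THETA_MIN))
        lb0 = float(np.clip(intercept, -40.0, 40.0))
    else:
        th0 = -0.01
        below = np.flatnonzero(y < 0.5 * peak)
        t_half0 = t[below[0]] if below.size else 0.5 * t[-1]
        lb0 = th0 * max(t_half0, t[1])

    def resid(p):
        a, lb, th = p
        return a / (1.0 + np.exp(np.clip(lb - th * t, -700, 700))) - y

    try:
        res = least_squares(
            resid,
            x0=[a0, lb0, th0],
            bounds=(
                [ALPHA_BOUNDS[0], -50.0, -THETA_MAX],
                [ALPHA_BOUNDS[1], 50.0, THETA_MAX],
            ),
            ftol=_TOL, xtol=_TOL, gtol=_TOL, max_nfev=MAX_NFEV,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return _failed_logistic(n, f"optimizer error: {exc}")
    if not res.success or not np.all(np.isfinite(res.x)):
        return _failed_logistic(n, "optimizer did not converge")
    a, lb, th = map(float, res.x)
    beta = float(np.exp(lb))
    rss = float(np.sum(res.fun**2))
    if abs(th) < THETA_MIN:
        return _failed_logistic(n, "degenerate rate")
    t_half = lb / th
    if not (0.0 < t_half <= t[-1]):
        return _failed_logistic(n, "half-life outside observation window")
    curve = a / (1.0 + beta * np.exp(-th * t))
    if curve[-1] >= curve[0]:
        return _failed_logistic(n, "fitted curve not decreasing")
    return LogisticFit(a, beta, th, t_half, rss, True, n)


def half_life(fit: LogisticFit) -> float:
    """Closed-form half-life of a fitted logistic: the t solving
    α/(1+β·e^(−θt)) = α/2, i.e. t½ = ln(β)/θ (independent of α)."""
    if not fit.converged:
        raise ValueError("half-life requires a converged fit")
    if fit.beta <= 0 or fit.theta == 0:
        raise ValueError("half-life undefined")
    if fit.beta == 1.0:
        return 0.0
    t = float(np.log(fit.beta) / fit.theta)
    if t < 0:
        raise ValueError("half-life undefined")
    return t


def fit_traceset(ts: TraceSet, model: str = "exponential") -> pd.DataFrame:
    """Fit every trace of an (aligned, ΔF/F) TraceSet.

    Returns the tidy fit table written to CSV by the pipeline: cell_id,
    condition, model, alpha, beta, theta, t_half, rss, converged, reason.
    Non-converged fits are kept in the table (flagged) so the run log can
    report them; downstream statistics must filter on ``converged``.
    """
    if model not in ("exponential", "logistic"):
        raise ValueError(f"unknown model {model!r}")
    rows = []
    for tr in ts:
        if model == "exponential":
            fit = fit_exponential(tr)
            beta = np.nan
            t_half = np.nan
        else:
            fit = fit_logistic(tr)
            beta = fit.beta
            t_half = fit.t_half
        rows.append(
            {
                "cell_id": tr.cell_id,
                "condition": tr.condition if tr.condition is not None else (ts.condition or ""),
                "well": tr.well,
                "model": model,
                "alpha": fit.alpha,
                "beta": beta,
                "theta": fit.theta,
                "t_half": t_half,
                "rss": fit.rss,
                "converged": fit.converged,
                "reason": fit.reason,
            }
        )
    df = pd.DataFrame(rows)
    n_bad = int((~df["converged"]).sum())
    if n_bad:
        log.info("fit_traceset(%s): %d/%d fits did not converge", model, n_bad, len(df))
    return df
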