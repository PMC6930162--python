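"""Single-cell fluorescence trace model: ΔF/F, stimulus alignment, QC.

A :class:`Trace` is one cell's fluorescence time series, either raw (``F``) or
baseline-normalized (``dff``, the fold change (F - F0)/F0 over a pre-stimulus
baseline window).  A :class:`TraceSet` collects the traces of one condition on
a shared acquisition grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger("sigprof")

__all__ = [
    "Trace",
    "TraceSet",
    "compute_dff",
    "align_to_stimulus",
    "qc_filter",
    "traceset_to_frame",
    "write_traces_csv",
    "read_traces_csv",
]


@dataclass
class Trace:
    """One cell's time-stamped fluorescence series.

    ``time`` must be strictly increasing (seconds).  Exactly one of ``F`` and
    ``dff`` is required at construction; ``dff`` is filled by
    :func:`compute_dff`.  ``baseline_window`` is a half-open index interval
    ``[start, stop)``; when ``None`` it defaults to all samples strictly
    before ``stimulus_time``.
    """

    cell_id: str
    time: np.ndarray
    F: Optional[np.ndarray] = None
    dff: Optional[np.ndarray] = None
    stimulus_time: float = 0.0
    baseline_window: Optional[Tuple[int, int]] = None
    well: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("F", "dff"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.time.shape:
                    raise ValueError(f"{name} and time must have equal length")
                setattr(self, name, arr)
        if self.F is None and self.dff is None:
            raise ValueError("one of F or dff is required")

    @property
    def n(self) -> int:
        return self.time.size

    def post_stimulus_mask(self) -> np.ndarray:
        return self.time >= self.stimulus_time

    def max_post_stimulus_dff(self) -> float:
        if self.dff is None:
            raise ValueError("dff not computed")
        mask = self.post_stimulus_mask()
        if not mask.any():
            raise ValueError("no post-stimulus samples")
        return float(np.max(self.dff[mask]))


@dataclass
class TraceSet:
    """A condition's traces on a common acquisition grid."""

    traces: list = field(default_factory=list)
    condition: Optional[str] = None
    well: Optional[str] = None
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate_grid()

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def validate_grid(self) -> None:
        if not self.traces:
            return
        ref = self.traces[0].time
        for tr in self.traces[1:]:
            if tr.time.shape != ref.shape or not np.allclose(tr.time, ref):
                raise ValueError("all traces in a TraceSet must share one time grid")

    def dff_matrix(self) -> np.ndarray:
        """Stack per-cell ΔF/F vectors into an (n_cells, n_samples) array."""
        if not self.traces:
            return np.empty((0, 0))
        rows = []
        for tr in self.traces:
            if tr.dff is None:
                raise ValueError(f"trace {tr.cell_id} has no dff")
            rows.append(tr.dff)
        return np.vstack(rows)

    def map(self, fn) -> "TraceSet":
        return TraceSet(
            traces=[fn(tr) for tr in self.traces],
            condition=self.condition,
            well=self.well,
            replicate=self.replicate,
        )


def _baseline_indices(trace: Trace) -> np.ndarray:
    if trace.baseline_window is not None:
        start, stop = trace.baseline_window
        idx = np.arange(start, stop)
        if idx.size == 0 or idx[0] < 0 or idx[-1] >= trace.n:
            raise ValueError("baseline_window out of range or empty")
        return idx
    idx = np.flatnonzero(trace.time < trace.stimulus_time)
    if idx.size == 0:
        raise ValueError("no pre-stimulus samples for baseline")
    return idx


def compute_dff(trace: Trace) -> Trace:
    """Baseline-normalize a raw trace: dff_t = (F_t - F0)/F0.

    F0 is the mean of F over the baseline window (all samples strictly before
    the stimulus when no window is given).  Raises on a non-physical baseline
    (F0 <= 0).
    """
    if trace.F is None:
        raise ValueError("trace has no raw fluorescence F")
    idx = _baseline_indices(trace)
    f0 = float(np.mean(trace.F[idx]))
    if f0 <= 0:
        raise ValueError(f"non-physical baseline mean {f0!r} (must be > 0)")
    return replace(trace, dff=(trace.F - f0) / f0)


def align_to_stimulus(trace: Trace, peak_align: bool = False) -> Trace:
    """Return the post-stimulus sub-trace with time re-origined to t = 0.

    Retention starts at the first sample at or after ``stimulus_time`` (or at
    the per-cell ΔF/F peak when ``peak_align`` is set).  At least 3 retained
    samples are required for any downstream fit.
    """
    if trace.stimulus_time > trace.time[-1]:
        raise ValueError("stimulus_time is after the last sample")
    start = int(np.searchsorted(trace.time, trace.stimulus_time, side="left"))
    if peak_align:
        if trace.dff is None:
            raise ValueError("peak alignment requires dff")
        start = start + int(np.argmax(trace.dff[start:]))
    if trace.n - start < 3:
        raise ValueError("fewer than 3 post-stimulus samples")
    sl = slice(start, None)
    return replace(
        trace,
        time=trace.time[sl] - trace.time[start],
        F=None if trace.F is None else trace.F[sl],
        dff=None if trace.dff is None else trace.dff[sl],
        stimulus_time=0.0,
        baseline_window=None,
    )


def qc_filter(ts: TraceSet, min_dff: float = 0.2) -> Tuple[TraceSet, TraceSet]:
    """Partition a TraceSet by the post-stimulus ΔF/F maximum.

    A trace is retained iff its maximum post-stimulus ΔF/F is at or above
    ``min_dff`` (cells below the threshold lack a positive response to the
    stimulus and are removed before fitting/clustering).  The partition is
    exhaustive and disjoint.
    """
    keep, drop = [], []
    for tr in ts:
        (keep if tr.max_post_stimulus_dff() >= min_dff else drop).append(tr)
    log.info(
        "qc_filter: retained %d / removed %d (min_dff=%.3g)",
        len(keep), len(drop), min_dff,
    )
    mk = lambda lst: TraceSet(lst, ts.condition, ts.well, ts.replicate)
    return mk(keep), mk(drop)


# ---------------------------------------------------------------------------
# tidy CSV interchange: cell_id, well, condition, time_s, F or dff
# ---------------------------------------------------------------------------

def traceset_to_frame(ts: TraceSet) -> pd.DataFrame:
    rows = []
    for tr in ts:
        value_col = "dff" if tr.dff is not None else "F"
        values = tr.dff if tr.dff is not None else tr.F
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "well": tr.well if tr.well is not None else (ts.well or ""),
                    "condition": tr.condition
                    if tr.condition is not None
                    else (ts.condition or ""),
                    "time_s": tr.time,
                    value_col: values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_traces_csv(ts: TraceSet, path) -> None:
    traceset_to_frame(ts).to_csv(path, index=False)


def read_traces_csv(path, stimulus_time: float = 0.0) -> TraceSet:
    """Load a tidy trace CSV, validating the common time grid.

    Every cell must cover the identical grid; traces with missing samples
    (gaps) are rejected rather than interpolated.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    value_col = "dff" if "dff" in df.columns else "F"
    if value_col not in df.columns:
        raise ValueError(f"{path}: needs an 'F' or 'dff' column")
    grid = None
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_s")
        t = sub["time_s"].to_numpy(float)
        if grid is None:
            grid = t
        elif t.shape != grid.shape or not np.allclose(t, grid):
            raise ValueError(f"{path}: cell {cell_id} does not match the common time grid")
        kwargs = {value_col: sub[value_col].to_numpy(float)}
        well = str(sub["well"].iloc[0]) if "well" in sub.columns else None
        cond = str(sub["condition"].iloc[0]) if "condition" in sub.columns else None
        traces.append(
            Trace(
                cell_id=str(cell_id),
                time=t,
                stimulus_time=stimulus_time,
                well=well,
                condition=cond,
                **kwargs,
            )
        )
    conds = {tr.condition for tr in traces}
    return TraceSet(traces, condition=conds.pop() if len(conds) == 1 else None)
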