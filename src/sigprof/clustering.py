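"""Signaling-profile clustering with PBM-index cluster-number selection.

Single-cell response traces (raw ΔF/F vectors on the common post-stimulus
grid) are segmented by seeded multi-restart k-means; the number of clusters
K is chosen over a candidate range (default 2-7) by maximizing the PBM
cluster-validity index

    PBM(K) = ((1/K) * (E1/EK) * DK)^2

where E1 is the total Euclidean distance of all traces to the global
centroid, EK the total distance of traces to their assigned centroids, and
DK the maximum pairwise centroid distance.  Conditions being compared are
pooled before clustering and the pooled assignments are split per condition
afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .traces import TraceSet

log = logging.getLogger("sigprof")

__all__ = [
    "ClusterScore",
    "ClusterModel",
    "pbm_index",
    "cluster_traces",
    "select_k",
    "profile_fractions",
    "fraction_summary",
]


@dataclass
class ClusterScore:
    """PBM score components for one candidate K."""

    K: int
    E1: float
    EK: float
    DK: float
    pbm: float


@dataclass
class ClusterModel:
    """A fitted clustering: centroids, assignments and per-K scores."""

    K_selected: int
    centroids: np.ndarray  # (K, n_samples)
    assignments: np.ndarray  # (n_traces,) in 0..K-1
    scores: List[ClusterScore] = field(default_factory=list)
    seed: int = 0
    inertia: float = np.nan

    def score_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"K": s.K, "E1": s.E1, "EK": s.EK, "DK": s.DK, "pbm": s.pbm} for s in self.scores]
        )


def _as_matrix(ts: Union[TraceSet, np.ndarray], znorm: bool = False) -> np.ndarray:
    X = ts.dff_matrix() if isinstance(ts, TraceSet) else np.asarray(ts, float)
    if X.ndim == 1:
        X = X[:, None]
    if znorm:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X


def pbm_index(
    X: Union[TraceSet, np.ndarray],
    assignments: Sequence[int],
    centroids: np.ndarray,
) -> ClusterScore:
    """Evaluate the PBM index of a given partition.

    Distances are Euclidean on the trace vectors.  Errors on K < 2 and on a
    degenerate partition where every point coincides with its centroid
    (EK = 0).
    """
    X = _as_matrix(X)
    assignments = np.asarray(assignments, int)
    centroids = np.asarray(centroids, float)
    if centroids.ndim == 1:
        centroids = centroids[:, None]
    K = centroids.shape[0]
    if K < 2:
        raise ValueError("PBM undefined for K<2")
    if assignments.shape[0] != X.shape[0]:
        raise ValueError("every vector needs exactly one assignment")
    if assignments.min() < 0 or assignments.max() >= K:
        raise ValueError("assignment labels out of range")
    grand = X.mean(axis=0)
    E1 = float(np.linalg.norm(X - grand, axis=1).sum())
    EK = float(np.linalg.norm(X - centroids[assignments], axis=1).sum())
    if EK == 0.0:
        raise ValueError("degenerate clustering (all points coincide with centroids)")
    diffs = centroids[:, None, :] - centroids[None, :, :]
    DK = float(np.linalg.norm(diffs, axis=2).max())
    pbm = ((1.0 / K) * (E1 / EK) * DK) ** 2
    return ClusterScore(K=K, E1=E1, EK=EK, DK=DK, pbm=pbm)


def _relabel_by_amplitude(centroids: np.ndarray, labels: np.ndarray):
    """Stable profile numbering: clusters ordered by ascending mean level."""
    order = np.argsort(centroids.mean(axis=1), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return centroids[order], remap[labels]


def cluster_traces(
    ts: Union[TraceSet, np.ndarray],
    K: int,
    seed: int = 0,
    restarts: int = 25,
    znorm: bool = False,
) -> ClusterModel:
    """K-means with ``restarts`` seeded initializations, keeping the lowest
    within-cluster sum of squares.  Deterministic under a fixed seed."""
    X = _as_matrix(ts, znorm=znorm)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of traces ({n})")
    km = KMeans(
        n_clusters=K,
        n_init=restarts,
        random_state=int(seed) % (2**32),
        algorithm="lloyd",
    ).fit(X)
    centroids, labels = _relabel_by_amplitude(km.cluster_centers_, km.labels_)
    model = ClusterModel(
        K_selected=K,
        centroids=centroids,
        assignments=labels,
        seed=seed,
        inertia=float(km.inertia_),
    )
    try:
        model.scores = [pbm_index(X, labels, centroids)]
    except ValueError:
        model.scores = []  # degenerate (e.g. K == n singletons)
    return model


def select_k(
    ts: Union[TraceSet, np.ndarray],
    k_range: Iterable[int] = range(2, 8),
    seed: int = 0,
    restarts: int = 25,
    znorm: bool = False,
) -> ClusterModel:
    """Cluster for every candidate K and keep the PBM-maximizing model.

    Ties break toward smaller K; the scores of every candidate are retained
    on the returned model for reporting.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or min(ks) < 2:
        raise ValueError("k_range must contain integers >= 2")
    X = _as_matrix(ts, znorm=znorm)
    if X.shape[0] < max(ks):
        raise ValueError("need at least max(k_range) traces")
    scores: List[ClusterScore] = []
    best: Optional[ClusterModel] = None
    best_score = -np.inf
    for K in ks:
        model = cluster_traces(X, K, seed=seed, restarts=restarts)
        if not model.scores:
            continue
        sc = model.scores[0]
        scores.append(sc)
        if sc.pbm > best_score:  # strict: ties keep the smaller K
            best_score = sc.pbm
            best = model
    if best is None:
        raise ValueError("no candidate K produced a non-degenerate clustering")
    best.scores = scores
    log.info(
        "select_k: K=%d (pbm=%.4g) over candidates %s", best.K_selected, best_score, ks
    )
    return best


def profile_fractions(
    model: ClusterModel,
    ts: Union[TraceSet, Sequence[TraceSet]],
) -> pd.DataFrame:
    """Per-condition, per-well fraction of cells in each profile.

    ``ts`` must contain, in order, exactly the traces that were clustered (a
    single pooled TraceSet or the list of per-condition sets whose
    concatenation was clustered); assignments are looked up, never re-fit.
    Fractions within one well sum to 1 over the profiles.
    """
    sets = [ts] if isinstance(ts, TraceSet) else list(ts)
    traces = [tr for s in sets for tr in s]
    if len(traces) != model.assignments.shape[0]:
        raise ValueError("trace count does not match the model's assignments")
    meta = []
    for s in sets:
        for tr in s:
            cond = tr.condition if tr.condition is not None else (s.condition or "")
            well = tr.well if tr.well is not None else s.well
            if well is None:
                raise ValueError(f"trace {tr.cell_id} has no well label")
            meta.append((cond, well))
    df = pd.DataFrame(meta, columns=["condition", "well"])
    df["profile"] = model.assignments
    K = model.centroids.shape[0]
    rows = []
    for (cond, well), sub in df.groupby(["condition", "well"], sort=True):
        n = len(sub)
        if n == 0:
            raise ValueError(f"condition {cond!r} well {well!r} has no retained cells")
        counts = sub["profile"].value_counts().reindex(range(K), fill_value=0)
        for profile, count in counts.items():
            rows.append(
                {
                    "condition": cond,
                    "well": well,
                    "profile": int(profile),
                    "n_cells": int(count),
                    "fraction": count / n,
                }
            )
    out = pd.DataFrame(rows)
    empty = {s.condition for s in sets if len(s) == 0 and s.condition}
    if empty:
        raise ValueError(f"conditions with zero retained cells: {sorted(empty)}")
    return out


def fraction_summary(fractions: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of per-well profile fractions within each condition."""
    g = fractions.groupby(["condition", "profile"])["fraction"]
    out = g.agg(mean="mean", sd="std", n_wells="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out
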