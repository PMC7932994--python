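"""Clustering of clonal expansion trajectories.

Clones passing a replicate-presence filter are summarized as
replicate-averaged UMI counts per timepoint, autoscaled per clone
(Z-score across timepoints), and grouped by k-means with multiple random
restarts.  The elbow curve over k and the repertoire impact of each
cluster reproduce the standard exploratory readouts for expansion
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .model import CloneCountTable

logger = logging.getLogger(__name__)


def filter_replicate_presence(
    table: CloneCountTable, min_replicates: int = 2, mode: str = "any"
) -> list[str]:
    """Clone ids kept by the replicate-presence rule.

    A clone counts as present at a timepoint when it is nonzero in at least
    ``min_replicates`` of that timepoint's replicate samples.  ``mode="any"``
    (default) keeps clones present at one or more timepoints;
    ``mode="every"`` requires presence at every timepoint.  The default
    reading avoids discarding genuine expanders that are absent before
    stimulation.
    """
    if mode not in ("any", "every"):
        raise ValueError("mode must be 'any' or 'every'")
    timepoints = sorted({s.timepoint for s in table.samples})
    present = []
    for t in timepoints:
        cols = [j for j, s in enumerate(table.samples) if s.timepoint == t]
        if len(cols) < min_replicates:
            raise ValueError(f"timepoint {t} has fewer than {min_replicates} samples")
        present.append((table.counts[:, cols] > 0).sum(axis=1) >= min_replicates)
    present = np.column_stack(present)
    keep = present.any(axis=1) if mode == "any" else present.all(axis=1)
    ids = [cid for cid, k in zip(table.clone_ids, keep) if k]
    logger.info("replicate-presence filter (%s, >=%d): kept %d/%d clones",
                mode, min_replicates, len(ids), table.n_clones)
    return ids


def build_trajectory_matrix(
    table: CloneCountTable, clone_ids: list[str] | None = None
) -> pd.DataFrame:
    """Replicate-averaged, per-clone autoscaled trajectories.

    Rows are clones, columns timepoints; each row is Z-scored (ddof=1)
    across timepoints.  Constant rows cannot be scaled and are mapped to
    all-zero rows with a warning, so cluster membership remains a partition
    of the filtered clone set.
    """
    timepoints = sorted({s.timepoint for s in table.samples})
    if clone_ids is not None:
        sub = table.subset_clones(clone_ids)
        # re-align to requested order, clones absent after subsetting keep 0s
        frame = sub.to_frame().reindex(clone_ids, fill_value=0)
        samples = sub.samples
    else:
        frame = table.to_frame()
        samples = table.samples
    means = np.column_stack([
        frame.loc[:, [s.sample_id for s in samples if s.timepoint == t]].mean(axis=1)
        for t in timepoints
    ])
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("%d constant trajectory row(s) set to zero", int(constant.sum()))
    sd[sd == 0] = 1.0
    z = (means - mu) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=frame.index, columns=timepoints)


@dataclass
class ClusterResult:
    """K-means partition of the trajectory matrix (cluster ids are 1-based)."""

    assignments: pd.Series          # clone_id -> cluster id in 1..k
    centroids: pd.DataFrame         # k x timepoints
    sse: float                      # total within-cluster sum of squares

    @property
    def k(self) -> int:
        return len(self.centroids)

    def membership(self) -> pd.DataFrame:
        """Per-cluster member count and percentage of clustered clones."""
        counts = self.assignments.value_counts().reindex(
            range(1, self.k + 1), fill_value=0
        )
        return pd.DataFrame(
            dict(cluster=counts.index, n=counts.to_numpy(),
                 pct=100.0 * counts.to_numpy() / max(1, len(self.assignments)))
        )


def kmeans_profiles(
    matrix: pd.DataFrame, k: int = 10, restarts: int = 25, seed: int = 0
) -> ClusterResult:
    """Best-of-``restarts`` k-means (Lloyd iterations, random initial
    centers drawn from the data, deterministic given ``seed``)."""
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds {len(matrix)} rows")
    km = KMeans(
        n_clusters=k, n_init=restarts, init="random", algorithm="lloyd",
        random_state=seed,
    ).fit(matrix.to_numpy())
    return ClusterResult(
        assignments=pd.Series(km.labels_ + 1, index=matrix.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=matrix.columns,
                               index=range(1, k + 1)),
        sse=float(km.inertia_),
    )


def _sse_of(matrix: np.ndarray, centers: np.ndarray) -> float:
    d2 = ((matrix[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def elbow_curve(
    matrix: pd.DataFrame, k_range: list[int] | range, restarts: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """SSE per k (each best-of-restarts) and a suggested elbow k.

    For each k beyond the smallest, the previous best centroids augmented
    with the farthest data point are used as one extra warm start, which
    makes the reported SSE curve non-increasing in k by construction.  The
    suggested k maximizes the perpendicular distance to the chord joining
    the curve's endpoints; the user's choice always overrides it.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > len(matrix):
        raise ValueError("k_range must lie within 1..n_rows")
    X = matrix.to_numpy()
    rows = []
    prev_centers = None
    for k in ks:
        res = kmeans_profiles(matrix, k=k, restarts=restarts, seed=seed)
        best_sse, best_centers = res.sse, res.centroids.to_numpy()
        if prev_centers is not None and len(prev_centers) < k:
            aug = prev_centers
            while len(aug) < k:
                d2 = ((X[:, None, :] - aug[None, :, :]) ** 2).sum(axis=2).min(axis=1)
                aug = np.vstack([aug, X[int(np.argmax(d2))]])
            warm = KMeans(n_clusters=k, init=aug, n_init=1, algorithm="lloyd").fit(X)
            if warm.inertia_ < best_sse:
                best_sse, best_centers = float(warm.inertia_), warm.cluster_centers_
        rows.append(dict(k=k, sse=best_sse))
        prev_centers = best_centers
    curve = pd.DataFrame(rows)

    if len(ks) == 1:
        return curve, ks[0]
    p0 = curve.iloc[0][["k", "sse"]].to_numpy(dtype=float)
    p1 = curve.iloc[-1][["k", "sse"]].to_numpy(dtype=float)
    chord = p1 - p0
    norm = np.hypot(*chord)
    pts = curve[["k", "sse"]].to_numpy(dtype=float)
    rel = pts - p0
    dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    suggested = int(curve["k"].iloc[int(np.argmax(dist))])
    return curve, suggested


def cluster_impact(
    result: ClusterResult, table: CloneCountTable, timepoint: int
) -> pd.Series:
    """Percentage of the repertoire occupied by each cluster's clones at a
    timepoint (mean over that timepoint's replicate frequencies)."""
    cols = [j for j, s in enumerate(table.samples) if s.timepoint == timepoint]
    if not cols:
        raise ValueError(f"timepoint {timepoint} not present")
    freq = table.frequencies()[:, cols].mean(axis=1)
    freq_by_clone = pd.Series(freq, index=table.clone_ids)
    impact = {}
    for c in range(1, result.k + 1):
        members = result.assignments.index[result.assignments == c]
        impact[c] = 100.0 * float(
            freq_by_clone.reindex(members, fill_value=0.0).sum()
        )
    return pd.Series(impact, name=f"impact_day{timepoint}")
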