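"""Superposition RMSD and greedy conformational clustering.

Provides weighted Kabsch superposition, RMSD time series against a
reference frame, the neighbour-count greedy ("gromos", Daura-style)
clustering of conformations under a pairwise-RMSD cutoff, and the
cluster-occupancy summary table (total frames, number of clusters,
probability of the biggest cluster, first/middle/last timestamps of its
members).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajio import IndexGroup, Trajectory

__all__ = [
    "RMSDSeries",
    "ClusterResult",
    "kabsch_superpose",
    "rmsd_series",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "summarize_clusters",
    "round_half_away",
]


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (report rounding; numpy rounds half to even)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class RMSDSeries:
    times: np.ndarray        # ps
    values: np.ndarray       # nm
    fit_group: str
    measure_group: str
    reference: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "rmsd_nm": self.values})


@dataclass
class ClusterResult:
    assignments: np.ndarray       # cluster id per frame (0 = biggest)
    cluster_sizes: np.ndarray     # descending
    centroids: np.ndarray         # frame index per cluster
    cutoff: float                 # nm

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)
        self.cluster_sizes = np.asarray(self.cluster_sizes, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=int)
        if self.cluster_sizes.sum() != len(self.assignments):
            raise ValueError("cluster sizes must sum to the frame count")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def probabilities(self) -> np.ndarray:
        return self.cluster_sizes / self.cluster_sizes.sum()


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the weighted RMSD. The
    rotation is always proper (det +1): the smallest singular direction is
    reflected when necessary, which is also the documented tie-break for
    degenerate (e.g. collinear) point sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("point sets must match and contain at least 3 points")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, not all zero")
    w = w / w.sum()
    mu_m = (w[:, None] * mobile).sum(axis=0)
    mu_r = (w[:, None] * reference).sum(axis=0)
    X = mobile - mu_m
    Y = reference - mu_r
    H = (w[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = X @ R.T
    rmsd = float(np.sqrt((w * ((fitted - Y) ** 2).sum(axis=1)).sum()))
    t = mu_r - mu_m @ R.T
    return R, t, rmsd


def _frame_rmsd(
    coords: np.ndarray,
    ref_coords: np.ndarray,
    fit_idx: np.ndarray,
    measure_idx: np.ndarray,
    weights: np.ndarray | None,
) -> float:
    R, t, _ = kabsch_superpose(coords[fit_idx], ref_coords[fit_idx], weights)
    moved = coords[measure_idx] @ R.T + t
    diff = moved - ref_coords[measure_idx]
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))


def rmsd_series(
    trajectory: Trajectory,
    fit_group: IndexGroup,
    measure_group: IndexGroup | None = None,
    reference_frame: int = 0,
    mass_weighted: bool = False,
) -> RMSDSeries:
    """RMSD of each frame from a reference frame after superposition.

    Each frame is first superposed on the reference over ``fit_group``; the
    RMSD is then taken over ``measure_group`` (defaults to the fit group).
    The value at the reference frame is zero by construction.
    """
    top = trajectory.topology
    if measure_group is None:
        measure_group = fit_group
    fit_idx = fit_group.indices(top)
    meas_idx = measure_group.indices(top)
    if not (0 <= reference_frame < trajectory.n_frames):
        raise ValueError("reference frame out of range")
    ref = trajectory.frames[reference_frame].coordinates
    w = top.masses[fit_idx] if mass_weighted else None
    values = np.array(
        [_frame_rmsd(fr.coordinates, ref, fit_idx, meas_idx, w)
         for fr in trajectory.frames]
    )
    return RMSDSeries(
        times=trajectory.times,
        values=values,
        fit_group=fit_group.name,
        measure_group=measure_group.name,
        reference=reference_frame,
    )


def pairwise_rmsd_matrix(
    trajectory: Trajectory,
    group: IndexGroup,
    frame_indices: np.ndarray | None = None,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Symmetric matrix of pairwise superposition RMSDs over ``group``."""
    top = trajectory.topology
    idx = group.indices(top)
    if frame_indices is None:
        frame_indices = np.arange(trajectory.n_frames)
    w = top.masses[idx] if mass_weighted else None
    coords = [trajectory.frames[int(i)].coordinates[idx] for i in frame_indices]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(coords[j], coords[i], w)
            mat[i, j] = mat[j, i] = r
    return mat


def gromos_cluster(distance_matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbour-count clustering of conformations (Daura et al. style).

    Repeatedly, the frame with the most neighbours within ``cutoff``
    (counting itself) becomes a centroid; it and its neighbours form a
    cluster and are removed from the pool. Ties on neighbour count are
    broken toward the lowest frame index. Clusters are reported by
    descending size (ties again by centroid index).
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    clusters: list[tuple[int, np.ndarray]] = []
    within = D <= cutoff
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(within[centroid] & remaining)[0]
        clusters.append((centroid, members))
        remaining[members] = False
    order = sorted(range(len(clusters)),
                   key=lambda k: (-len(clusters[k][1]), clusters[k][0]))
    sizes, centroids = [], []
    for new_id, k in enumerate(order):
        centroid, members = clusters[k]
        assignments[members] = new_id
        sizes.append(len(members))
        centroids.append(centroid)
    return ClusterResult(
        assignments=assignments,
        cluster_sizes=np.array(sizes),
        centroids=np.array(centroids),
        cutoff=float(cutoff),
    )


def summarize_clusters(
    result: ClusterResult, frame_times: np.ndarray
) -> dict:
    """Occupancy summary of a clustering, in report units.

    Returns total frame count, number of clusters, the biggest cluster's
    probability (size/total, reported rounded half away from zero to 2
    decimals; full precision under ``biggest_probability_exact``), the
    probabilities of the remaining clusters, and the first / middle / last
    timestamps of the biggest cluster's members (middle = member at ordinal
    ⌈k/2⌉ of k members in time order).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frame_times) != len(result.assignments):
        raise ValueError("frame_times must cover all assigned frames")
    total = int(result.cluster_sizes.sum())
    probs = result.probabilities
    members = np.nonzero(result.assignments == 0)[0]
    t = np.sort(frame_times[members])
    k = len(t)
    middle = t[int(np.ceil(k / 2)) - 1]
    return {
        "total_frames": total,
        "n_clusters": int(result.n_clusters),
        "biggest_probability": round_half_away(float(probs[0]), 2),
        "biggest_probability_exact": float(probs[0]),
        "biggest_size": int(result.cluster_sizes[0]),
        "other_probabilities": [round_half_away(float(p), 2) for p in probs[1:]],
        "biggest_first_ps": float(t[0]),
        "biggest_middle_ps": float(middle),
        "biggest_last_ps": float(t[-1]),
    }
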