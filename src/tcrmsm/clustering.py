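"""Seed-structure extraction and microstating.

Two clustering steps feed the pipeline: average-linkage hierarchical
clustering of pairwise post-superposition RMSD with a distance cutoff
(default 1.2 Å), which extracts the medoid seed structures from an enhanced
sampling run; and k-means in tICA space (150 microstates at production
scale), which discretises trajectories for Markov-state model estimation.

RMSD is computed on backbone atoms of the configured selections, each pair
optimally superposed (Kabsch). The pairwise matrix is O(n²); desk-scale
frame counts are assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structure_io import Trajectory

__all__ = [
    "ClusterResult",
    "DiscreteTrajectory",
    "superpose",
    "pairwise_rmsd",
    "average_linkage_cluster",
    "kmeans",
]


@dataclass
class ClusterResult:
    labels: np.ndarray          # cluster id per frame, 0-based
    representatives: np.ndarray  # medoid frame index per cluster
    cutoff: float               # Å
    linkage: str = "average"

    @property
    def n_clusters(self) -> int:
        return self.representatives.size


@dataclass
class DiscreteTrajectory:
    """State ids per frame (0-based) over n_states."""

    states: np.ndarray
    n_states: int
    frame_interval: float       # ns

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size and (self.states.min() < 0 or self.states.max() >= self.n_states):
            raise ValueError("state ids must lie in [0, n_states)")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              subset: np.ndarray | None = None):
    """Least-squares rigid superposition (Kabsch).

    Returns (rotation 3×3, translation 3, rmsd Å) such that
    ``mobile @ R.T + t`` best fits ``reference`` over ``subset`` (all atoms
    when None); the RMSD is post-superposition over the subset.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    idx = np.arange(mobile.shape[0]) if subset is None else np.asarray(subset, int)
    if idx.size < 3:
        raise ValueError("superposition needs >= 3 atoms")
    x = mobile[idx]
    y = reference[idx]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        raise ValueError("degenerate (collinear) atom subset for superposition")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    fitted = x0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y0) ** 2, axis=1))))
    return rot, trans, rmsd


def pairwise_rmsd(traj: Trajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise-optimal RMSD over the selected atoms."""
    n = traj.n_frames
    coords = traj.frames if selection is None else traj.frames[:, np.asarray(selection, int)]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose(coords[i], coords[j])
            mat[i, j] = mat[j, i] = r
    return mat


def average_linkage_cluster(traj: Trajectory, selection: np.ndarray | None,
                            cutoff: float,
                            distance_matrix: np.ndarray | None = None) -> ClusterResult:
    """Average-linkage agglomeration on pairwise RMSD with a distance cutoff.

    Merging stops once the smallest average inter-cluster distance exceeds
    ``cutoff`` (scipy ``fcluster`` with the distance criterion); each cluster
    is represented by its medoid — the member with minimal mean in-cluster
    distance, ties to the lower frame index.
    """
    dmat = pairwise_rmsd(traj, selection) if distance_matrix is None else np.asarray(distance_matrix, float)
    if not np.all(np.isfinite(dmat)):
        raise ValueError("pairwise RMSD matrix contains non-finite values")
    n = dmat.shape[0]
    if n == 1:
        return ClusterResult(np.zeros(1, int), np.zeros(1, int), cutoff)
    z = linkage(squareform(dmat, checks=False), method="average")
    flat = fcluster(z, t=cutoff, criterion="distance") - 1
    # renumber clusters by first appearance for determinism
    order: dict[int, int] = {}
    labels = np.empty(n, int)
    for i, c in enumerate(flat):
        if c not in order:
            order[c] = len(order)
        labels[i] = order[c]
    reps = []
    for c in range(len(order)):
        members = np.flatnonzero(labels == c)
        mean_d = dmat[np.ix_(members, members)].mean(axis=1)
        reps.append(members[int(np.argmin(mean_d))])
    return ClusterResult(labels, np.array(reps, int), cutoff)


def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = points[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((points - centers[j]) ** 2, axis=1))
    return centers


def kmeans(points, k: int, seed: int, max_iter: int = 300,
           tol: float = 1e-8, frame_interval: float | None = None):
    """Lloyd's k-means with k-means++ seeding; deterministic for a fixed seed.

    Accepts a FeatureMatrix or an (n, d) array. The within-cluster sum of
    squares is asserted non-increasing at every iteration; an emptied cluster
    is re-seeded at the point farthest from its assigned center. Returns
    (DiscreteTrajectory, centers, objective_history).
    """
    if hasattr(points, "values") and hasattr(points, "frame_interval"):
        frame_interval = frame_interval or points.frame_interval
        points = points.values
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n_distinct = np.unique(pts, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(pts, k, rng)
    prev_obj = np.inf
    history: list[float] = []
    labels = np.zeros(pts.shape[0], int)
    for _ in range(max_iter):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2) \
            if pts.shape[0] * k <= 2_000_000 else _chunked_d2(pts, centers)
        labels = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(pts.shape[0]), labels].sum())
        assert obj <= prev_obj + 1e-9 * max(1.0, abs(prev_obj)), \
            "k-means objective increased"
        history.append(obj)
        new_centers = centers.copy()
        shift = 0.0
        for j in range(k):
            mask = labels == j
            if not mask.any():
                far = int(np.argmax(d2[np.arange(pts.shape[0]), labels]))
                new_centers[j] = pts[far]
                shift = np.inf
                continue
            new_centers[j] = pts[mask].mean(axis=0)
            shift = max(shift, float(np.linalg.norm(new_centers[j] - centers[j])))
        centers = new_centers
        prev_obj = obj
        if shift < tol:
            break
    dtraj = DiscreteTrajectory(labels, k, frame_interval or 1.0)
    return dtraj, centers, np.array(history)


def _chunked_d2(pts: np.ndarray, centers: np.ndarray, chunk: int = 8192) -> np.ndarray:
    out = np.empty((pts.shape[0], centers.shape[0]))
    for start in range(0, pts.shape[0], chunk):
        block = pts[start:start + chunk]
        out[start:start + chunk] = (
            (block ** 2).sum(axis=1)[:, None]
            - 2.0 * block @ centers.T
            + (centers ** 2).sum(axis=1)[None, :]
        )
    np.maximum(out, 0.0, out=out)
    return out
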