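"""DP-means clustering with a radius parameter, plus exact triangle pruning.

DP-means is the small-variance deterministic limit of a Dirichlet-process
Gaussian mixture: a k-means-like sweep where any element further than a
radius ``lambda`` from every current centroid seeds a new cluster, so the
number of clusters is controlled by the radius instead of being fixed in
advance. Setting the radius to the read error-rate cutoff lets the
clustering decide the number of templates from the data.

The algorithm is order-dependent; element order is taken as given, which
makes runs reproducible (permuting the input may change the result — a
property of the algorithm, not an implementation accident).

``dp_means_pruned`` produces the *identical* clustering while skipping
most distance evaluations: centroids are grouped into coarse
"meta-centroids", read-to-meta distances are computed once in the
Euclidean kmer domain (a true metric), and the triangle inequality
``|d(read, meta) - d(centroid, meta)| <= d(read, centroid)`` rules out
centroids that are provably beyond the radius. The scaled corrected
distance is monotone in Euclidean distance for fixed sequence lengths, so
the pruning is conservative and exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import DEFAULT_K

SCALED_KMER = "scaled_kmer"
EUCLIDEAN = "euclidean"

# Radius multiplier for clustering centroids into meta-centroids. Coarse
# super-clusters keep the triangle bounds tight with few meta-centroids;
# pruning exactness does not depend on this value.
META_RADIUS_FACTOR = 4.0


@dataclass
class DpMeansConfig:
    """Radius, iteration cap and distance choice for DP-means."""

    radius: float = 0.01
    max_iterations: int = 100
    distance: str = SCALED_KMER
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.distance not in (SCALED_KMER, EUCLIDEAN):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass
class Clustering:
    """Assignments, per-cluster centroids and sizes.

    ``centroid_lengths`` carries the mean originating-sequence length per
    cluster when the scaled kmer distance was used. ``distance_evals``
    counts full-vector distance computations (for pruning diagnostics).
    """

    assignments: np.ndarray
    centroids: np.ndarray
    sizes: np.ndarray
    centroid_lengths: np.ndarray | None = None
    distance_evals: int = 0
    iterations: int = 0

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster)


def _scaled_sq_threshold(radius: float, k: int, len_a, len_b) -> np.ndarray:
    """Squared-Euclidean equivalent of ``scaled distance < radius``."""
    return 2.0 * k * radius * 0.5 * (np.asarray(len_a, dtype=float) + len_b)


class _State:
    """Mutable centroid state shared by the naive and pruned sweeps."""

    def __init__(self, dim: int, scaled: bool, k: int, radius: float):
        self.C = np.empty((0, dim))
        self.lengths = np.empty(0)
        self.scaled = scaled
        self.k = k
        self.radius = radius
        self.evals = 0

    def seed(self, point: np.ndarray, length: float) -> int:
        self.C = np.vstack([self.C, point[None, :]])
        self.lengths = np.append(self.lengths, length)
        return self.C.shape[0] - 1

    def distances_sq(self, point: np.ndarray) -> np.ndarray:
        diff = self.C - point
        self.evals += self.C.shape[0]
        return np.einsum("ij,ij->i", diff, diff)

    def nearest(self, point: np.ndarray, length: float):
        """(index, within_radius) of nearest centroid; (-1, False) if none."""
        if self.C.shape[0] == 0:
            return -1, False
        sq = self.distances_sq(point)
        if self.scaled:
            dist = sq / (2.0 * self.k * 0.5 * (length + self.lengths))
        else:
            dist = np.sqrt(sq)
        j = int(np.argmin(dist))
        return j, bool(dist[j] < self.radius)

    def recompute(self, points: np.ndarray, lengths: np.ndarray,
                  assignments: np.ndarray) -> np.ndarray:
        """Average members into centroids, drop empties, relabel compactly.

        Returns the relabelled assignment array (labels in order of first
        appearance, so results are deterministic).
        """
        m = self.C.shape[0]
        sizes = np.bincount(assignments, minlength=m)
        keep = np.flatnonzero(sizes > 0)
        relabel = np.full(m, -1, dtype=int)
        relabel[keep] = np.arange(keep.size)
        assignments = relabel[assignments]
        sums = np.zeros((keep.size, points.shape[1]))
        np.add.at(sums, assignments, points)
        len_sums = np.zeros(keep.size)
        np.add.at(len_sums, assignments, lengths)
        counts = np.bincount(assignments, minlength=keep.size).astype(float)
        self.C = sums / counts[:, None]
        self.lengths = len_sums / counts
        return assignments


def _as_matrix(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty 2-D array")
    return pts


def _finalize(state: _State, points, lengths, assignments, iterations) -> Clustering:
    sizes = np.bincount(assignments, minlength=state.C.shape[0])
    return Clustering(
        assignments=assignments,
        centroids=state.C.copy(),
        sizes=sizes,
        centroid_lengths=state.lengths.copy() if state.scaled else None,
        distance_evals=state.evals,
        iterations=iterations,
    )


def dp_means(points, config: DpMeansConfig, lengths=None) -> Clustering:
    """Cluster points with DP-means; deterministic given input order.

    ``lengths`` (originating sequence lengths) is required for the scaled
    kmer distance and ignored for plain Euclidean distance.
    """
    pts = _as_matrix(points)
    n = pts.shape[0]
    scaled = config.distance == SCALED_KMER
    if scaled:
        if lengths is None:
            raise ValueError("scaled kmer distance requires sequence lengths")
        lens = np.asarray(lengths, dtype=float)
    else:
        lens = np.zeros(n)
    state = _State(pts.shape[1], scaled, config.k, config.radius)
    assignments = np.full(n, -1, dtype=int)
    prev = None
    iterations = 0
    for _ in range(config.max_iterations):
        iterations += 1
        for i in range(n):
            j, within = state.nearest(pts[i], lens[i])
            assignments[i] = j if within else state.seed(pts[i], lens[i])
        assignments = state.recompute(pts, lens, assignments)
        if prev is not None and np.array_equal(prev, assignments):
            break
        prev = assignments.copy()
    return _finalize(state, pts, lens, assignments, iterations)


def dp_means_pruned(points, config: DpMeansConfig, lengths) -> Clustering:
    """DP-means with exact meta-centroid triangle pruning.

    Produces a clustering identical to :func:`dp_means` on the same input
    and order; only the amount of distance computation differs. Requires
    the scaled kmer distance (pruning bounds live in the Euclidean domain).
    """
    if config.distance != SCALED_KMER:
        raise ValueError("pruned DP-means requires the scaled kmer distance")
    pts = _as_matrix(points)
    n = pts.shape[0]
    lens = np.asarray(lengths, dtype=float)
    state = _State(pts.shape[1], True, config.k, config.radius)
    assignments = np.full(n, -1, dtype=int)

    # First pass: identical to the naive sweep (there is nothing to prune
    # against yet).
    iterations = 1
    for i in range(n):
        j, within = state.nearest(pts[i], lens[i])
        assignments[i] = j if within else state.seed(pts[i], lens[i])
    assignments = state.recompute(pts, lens, assignments)
    prev = assignments.copy()

    # Meta-centroids: cluster the first-pass centroids coarsely, once.
    meta_cfg = DpMeansConfig(
        radius=META_RADIUS_FACTOR * config.radius,
        max_iterations=config.max_iterations,
        distance=SCALED_KMER,
        k=config.k,
    )
    meta = dp_means(state.C, meta_cfg, lengths=state.lengths)
    metas = meta.centroids
    # Read-to-meta Euclidean distances: computed once, reused every pass.
    R = np.sqrt(
        np.maximum(
            (pts**2).sum(axis=1)[:, None]
            - 2.0 * pts @ metas.T
            + (metas**2).sum(axis=1)[None, :],
            0.0,
        )
    )
    state.evals += n * metas.shape[0]

    for _ in range(config.max_iterations - 1):
        iterations += 1
        CM = np.sqrt(
            np.maximum(
                (state.C**2).sum(axis=1)[:, None]
                - 2.0 * state.C @ metas.T
                + (metas**2).sum(axis=1)[None, :],
                0.0,
            )
        )
        state.evals += state.C.shape[0] * metas.shape[0]
        for i in range(n):
            # CM is kept in sync with the centroid list: a centroid seeded
            # mid-pass *is* its seeding point, so its meta-distance row is
            # that point's row of R (no extra computation needed).
            lower = np.abs(CM - R[i][None, :]).max(axis=1)
            thresh_sq = _scaled_sq_threshold(
                config.radius, config.k, lens[i], state.lengths
            )
            # <= keeps the candidate set a superset under either boundary
            # rule; pruning stays conservative and therefore exact.
            candidates = np.flatnonzero(lower * lower <= thresh_sq)
            new = -1
            if candidates.size:
                diff = state.C[candidates] - pts[i]
                sq = np.einsum("ij,ij->i", diff, diff)
                state.evals += candidates.size
                dist = sq / (
                    2.0 * config.k * 0.5 * (lens[i] + state.lengths[candidates])
                )
                jj = int(np.argmin(dist))
                if dist[jj] < config.radius:
                    new = int(candidates[jj])
            if new < 0:
                new = state.seed(pts[i], lens[i])
                CM = np.vstack([CM, R[i][None, :]])
            assignments[i] = new
        assignments = state.recompute(pts, lens, assignments)
        if np.array_equal(prev, assignments):
            break
        prev = assignments.copy()
    return _finalize(state, pts, lens, assignments, iterations)
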