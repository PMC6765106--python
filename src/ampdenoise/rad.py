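"""Robust Amplicon Denoising (RAD): cluster-and-consensus denoising for the
long-and-inaccurate regime.

When few or no reads are error free, templates must be reconstructed by
grouping reads and averaging their noise away. RAD stays in the kmer
domain throughout the grouping stages:

1. Coarse clustering: DP-means over scaled kmer vectors with the radius
   set to the error-rate filtering cutoff (default 0.01), accelerated by
   exact meta-centroid triangle pruning.
2. Recursive fine splitting: within a cluster, project reads onto the few
   (default 6) highest-variance kmer coordinates — after discarding kmer
   pairs related by a single homopolymer length edit, so the dominant
   indel error mode cannot drive a split — and re-cluster with Euclidean
   distance at a radius of 1. A single base difference perturbs at least
   ~k kmers, so genuine single-base variants separate cleanly. Candidate
   sub-clusters are kept only when they are too large to be one-site error
   artifacts of the dominant sub-cluster (the same Bonferroni-corrected
   Poisson tail test FAD uses); noise shards that fail the test are folded
   back into the nearest surviving sub-cluster. Splitting recurses until
   no cluster shows evidence of heterogeneity.
3. Consensus: each final cluster is polished into a single template
   sequence (see :mod:`ampdenoise.consensus`); identical consensus
   sequences are merged and cluster sizes become template counts.

Unlike FAD, cluster abundances here are already total-molecule counts, so
the Poisson null is parameterized directly by the observed parent size
(no error-free-fraction correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusConfig, cluster_consensus
from .dpmeans import EUCLIDEAN, SCALED_KMER, DpMeansConfig, dp_means, dp_means_pruned
from .fad import offspring_pvalue
from .kmers import DEFAULT_K, kmer_matrix, top_variance_kmers
from .populations import TemplateSet
from .seq_io import Read

logger = logging.getLogger(__name__)


@dataclass
class RadConfig:
    """Clustering radii, projection sizes and split significance level."""

    coarse_radius: float = 0.01
    m_pool: int = 20
    n_project: int = 6
    # Projected coordinates are integer kmer counts, so reads from the same
    # template sit at distance 0 or 1 (one perturbed kmer) from their
    # group, while reads differing at two or more of the selected kmers sit
    # at >= sqrt(2). The radius is placed between those two lattice values:
    # a single perturbed kmer must never separate a read, two always do,
    # and fractional centroid drift cannot flip either decision.
    split_radius: float = 1.2
    alpha: float = 0.01
    max_depth: int = 20
    k: int = DEFAULT_K
    max_iterations: int = 100
    # Clusters below this size are not reported as templates; their reads
    # are assigned to the nearest surviving template (minimum corrected
    # kmer distance), so reported frequencies still describe the whole
    # read population. The default keeps every cluster, singletons
    # included.
    min_cluster: int = 1

    def __post_init__(self) -> None:
        if not (self.m_pool >= self.n_project >= 1):
            raise ValueError("require m_pool >= n_project >= 1")
        if self.split_radius <= 0:
            raise ValueError("split_radius must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class Cluster:
    """A set of reads (by index) sharing one putative template.

    ``kmers`` is the full dataset kmer matrix, shared between clusters;
    ``matrix`` views this cluster's rows.
    """

    member_indices: np.ndarray
    kmers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        if self.member_indices.size < 1:
            raise ValueError("cluster must have at least one member")

    @property
    def size(self) -> int:
        return int(self.member_indices.size)

    @property
    def matrix(self) -> np.ndarray:
        return self.kmers[self.member_indices]


@dataclass
class DatasetStats:
    """Whole-dataset error statistics feeding the split significance test."""

    mean_errors: float
    mean_length: float

    @classmethod
    def from_reads(cls, reads: list[Read]) -> "DatasetStats":
        return cls(
            mean_errors=float(np.mean([r.expected_errors for r in reads])),
            mean_length=float(np.mean([len(r) for r in reads])),
        )


def coarse_cluster(
    reads: list[Read], config: RadConfig | None = None, kmers: np.ndarray | None = None
) -> list[Cluster]:
    """Partition reads by pruned DP-means over scaled kmer distance.

    Reads are processed in order of increasing expected errors (ties by
    input position). DP-means is order dependent, and a read that seeds a
    cluster can never leave it (its own centroid sits at distance zero);
    were noisy reads processed first, the high-error tail would freeze
    into singleton clusters before any template-like centroid exists.
    Quality-first ordering seeds centroids from near-noiseless reads, so
    the noisy tail falls into the template clusters it belongs to.
    """
    config = config or RadConfig()
    if kmers is None:
        kmers = kmer_matrix([r.sequence for r in reads], config.k)
    lengths = np.asarray([len(r) for r in reads], dtype=float)
    errors = np.asarray([r.expected_errors for r in reads])
    order = np.argsort(errors, kind="stable")
    clustering = dp_means_pruned(
        kmers.astype(float)[order],
        DpMeansConfig(
            radius=config.coarse_radius,
            max_iterations=config.max_iterations,
            distance=SCALED_KMER,
            k=config.k,
        ),
        lengths[order],
    )
    assignments = np.empty(order.size, dtype=int)
    assignments[order] = clustering.assignments
    return [
        Cluster(member_indices=np.flatnonzero(assignments == c), kmers=kmers)
        for c in range(clustering.n_clusters)
    ]


def split_once(
    cluster: Cluster, config: RadConfig, stats: DatasetStats
) -> list[Cluster]:
    """Attempt one high-variance-kmer split of a cluster.

    Returns the (size-ordered) sub-clusters when the split is accepted, or
    ``[cluster]`` unchanged when there is no usable projection, the
    projected clustering is trivial, or no candidate sub-cluster survives
    the Poisson size test.
    """
    if cluster.size < 2:
        return [cluster]
    sub = cluster.matrix
    selected = top_variance_kmers(sub, config.k, config.m_pool, config.n_project)
    if not selected:
        return [cluster]
    projected = sub[:, selected].astype(float)
    # DP-means is order dependent: were a rare multi-kmer deviant processed
    # first it would seed a centroid that then attracts single-kmer
    # deviants lying half-way between it and the dominant pattern. Feeding
    # the reads in descending projected-pattern abundance (ties broken
    # lexicographically) lets dense patterns seed first, so noise deviants
    # fall into their parent pattern's cluster.
    patterns, inverse, pattern_counts = np.unique(
        projected, axis=0, return_inverse=True, return_counts=True
    )
    rank = np.lexsort(tuple(patterns.T[::-1]) + (-pattern_counts,))
    rank_of = np.empty(rank.size, dtype=int)
    rank_of[rank] = np.arange(rank.size)
    order = np.argsort(rank_of[inverse], kind="stable")
    clustering = dp_means(
        projected[order],
        DpMeansConfig(
            radius=config.split_radius,
            max_iterations=config.max_iterations,
            distance=EUCLIDEAN,
        ),
    )
    assignments = np.empty(order.size, dtype=int)
    assignments[order] = clustering.assignments
    if clustering.n_clusters < 2:
        return [cluster]
    sizes = clustering.sizes
    largest = int(np.argmax(sizes))  # ties: lowest label
    passing = [largest]
    failing = []
    for label in range(clustering.n_clusters):
        if label == largest:
            continue
        # Under the null every read in the cluster is the same template, so
        # the parent abundance is the whole cluster size (already a
        # total-molecule count; no error-free-fraction correction).
        p = offspring_pvalue(
            parent_count=float(cluster.size),
            offspring_count=int(sizes[label]),
            f0=1.0,
            mean_errors=stats.mean_errors,
            mean_length=stats.mean_length,
        )
        (passing if p <= config.alpha else failing).append(label)
    if len(passing) == 1:
        return [cluster]
    # Fold noise shards into the nearest surviving sub-cluster (projected
    # centroid distance) so the partition is conserved.
    groups = {label: [label] for label in passing}
    if failing:
        pass_centroids = clustering.centroids[passing]
        for label in failing:
            diff = pass_centroids - clustering.centroids[label]
            nearest = passing[int(np.argmin(np.einsum("ij,ij->i", diff, diff)))]
            groups[nearest].append(label)
    children = []
    for label in passing:
        mask = np.isin(assignments, groups[label])
        children.append(
            Cluster(
                member_indices=cluster.member_indices[np.flatnonzero(mask)],
                kmers=cluster.kmers,
            )
        )
    children.sort(key=lambda c: (-c.size, int(c.member_indices[0])))
    return children


def refine(
    clusters: list[Cluster], config: RadConfig, stats: DatasetStats
) -> list[Cluster]:
    """Recursively split clusters until no split is accepted.

    A rejected split is terminal for that cluster. The recursion depth is
    capped at ``max_depth`` (``max_depth=0`` returns the input verbatim);
    hitting the cap logs a warning.
    """
    final: list[Cluster] = []
    queue: list[tuple[Cluster, int]] = [(c, 0) for c in clusters]
    while queue:
        cluster, depth = queue.pop(0)
        if depth >= config.max_depth:
            if cluster.size >= 2 and config.max_depth > 0:
                logger.warning(
                    "refinement depth cap %d reached for a cluster of %d reads",
                    config.max_depth,
                    cluster.size,
                )
            final.append(cluster)
            continue
        children = split_once(cluster, config, stats)
        if len(children) == 1:
            final.append(cluster)
        else:
            queue.extend((child, depth + 1) for child in children)
    return final


def rad_denoise(
    reads: list[Read],
    config: RadConfig | None = None,
    consensus_config: ConsensusConfig | None = None,
) -> TemplateSet:
    """Full RAD pipeline: coarse cluster, refine, consensus, merge."""
    config = config or RadConfig()
    consensus_config = consensus_config or ConsensusConfig()
    if not reads:
        raise ValueError("rad_denoise needs at least one read")
    sequences = [r.sequence for r in reads]
    kmers = kmer_matrix(sequences, config.k)
    stats = DatasetStats.from_reads(reads)
    clusters = coarse_cluster(reads, config, kmers=kmers)
    logger.info("coarse clustering: %d clusters", len(clusters))
    clusters = refine(clusters, config, stats)
    logger.info("after refinement: %d clusters", len(clusters))
    merged: dict[str, int] = {}
    orphan_indices: list[int] = []
    small = [c for c in clusters if c.size < config.min_cluster]
    kept = [c for c in clusters if c.size >= config.min_cluster]
    if not kept:  # degenerate: everything below threshold; report all
        kept, small = clusters, []
    for cluster in kept:
        members = [sequences[i] for i in cluster.member_indices]
        template = cluster_consensus(
            members, counts=cluster.matrix, config=consensus_config, k=config.k
        )
        merged[template] = merged.get(template, 0) + cluster.size
    for cluster in small:
        orphan_indices.extend(int(i) for i in cluster.member_indices)
    entries = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = np.asarray([c for _, c in entries], dtype=np.int64)
    if orphan_indices:
        # Re-home reads of sub-threshold clusters to the nearest template,
        # FAD-style, so frequencies reflect the full read population.
        template_kmers = kmer_matrix([s for s, _ in entries], config.k).astype(float)
        orphans = kmers[orphan_indices].astype(float)
        sq = (
            (orphans**2).sum(axis=1)[:, None]
            - 2.0 * orphans @ template_kmers.T
            + (template_kmers**2).sum(axis=1)[None, :]
        )
        priority = np.lexsort((np.arange(counts.size), -counts))
        choice = priority[np.argmin(sq[:, priority], axis=1)]
        counts += np.bincount(choice, minlength=counts.size)
    return TemplateSet(
        sequences=[s for s, _ in entries],
        counts=counts,
        frequencies=counts / counts.sum(),
    )
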