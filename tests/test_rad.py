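import numpy as np
import pytest

from ampdenoise.fad import fad_denoise
from ampdenoise.kmers import kmer_matrix
from ampdenoise.populations import WeightedPopulation
from ampdenoise.rad import (
    Cluster,
    DatasetStats,
    RadConfig,
    coarse_cluster,
    rad_denoise,
    refine,
    split_once,
)
from ampdenoise.simulate import (
    ErrorProfile,
    default_seed_sequence,
    generate_templates,
    simulate_reads,
)

from conftest import make_read, substitute, unique_kmer_sequence

ZERO_NOISE = ErrorProfile(sub_rate=0.0, indel_base_rate=0.0)


def _cluster_of(seqs):
    K = kmer_matrix(seqs)
    return Cluster(member_indices=np.arange(len(seqs)), kmers=K)


def _stats(n_errors=1.0, length=2600.0):
    return DatasetStats(mean_errors=n_errors, mean_length=length)


@pytest.fixture(scope="module")
def backbone():
    return unique_kmer_sequence(800, seed=53)


class TestCoarseCluster:
    def test_two_divergent_templates_pure_clusters(self, backbone):
        rng = np.random.default_rng(3)
        t1 = backbone
        t2 = list(backbone)  # ~5% divergence
        for p in rng.choice(len(t2), size=40, replace=False):
            t2[p] = "ACGT"[rng.integers(0, 4)]
        t2 = "".join(t2)
        pop = WeightedPopulation([t1, t2], np.array([0.5, 0.5]))
        # filtered at ~0.5%/base, indel-heavy, with CCS-like per-read
        # accuracy variation below the cutoff
        profile = ErrorProfile(sub_rate=1e-3, indel_base_rate=4e-3,
                               rate_spread=0.75)
        reads, gt = simulate_reads(
            pop, 60, profile, 5, origins=np.repeat([0, 1], 30)
        )
        clusters = coarse_cluster(reads)
        assert len(clusters) == 2
        for c in clusters:
            origins = gt.read_origins[c.member_indices]
            assert len(set(origins.tolist())) == 1

    def test_identical_reads_single_cluster(self, backbone):
        reads = [make_read(backbone) for _ in range(10)]
        assert len(coarse_cluster(reads)) == 1

    def test_single_read_singleton(self, backbone):
        clusters = coarse_cluster([make_read(backbone)])
        assert len(clusters) == 1 and clusters[0].size == 1


class TestSplitOnce:
    def test_two_variants_one_substitution_apart(self, backbone):
        t1, t2 = backbone, substitute(backbone, 400)
        cluster = _cluster_of([t1] * 100 + [t2] * 100)
        children = split_once(cluster, RadConfig(), _stats())
        assert len(children) == 2
        assert sorted(c.size for c in children) == [100, 100]
        sides = [set(c.member_indices.tolist()) for c in children]
        assert set(range(100)) in sides and set(range(100, 200)) in sides

    def test_homogeneous_cluster_unchanged(self, backbone):
        # substitution noise only: fragments fail the Poisson size test
        rng = np.random.default_rng(9)
        members = []
        for _ in range(120):
            s = backbone
            if rng.random() < 0.3:
                s = substitute(s, int(rng.integers(10, 700)))
            members.append(s)
        cluster = _cluster_of(members)
        children = split_once(cluster, RadConfig(), _stats(0.3, 800.0))
        assert len(children) == 1
        assert children[0] is cluster

    def test_homopolymer_length_variation_not_split(self, backbone):
        with_run = backbone[:300] + "AAAAAA" + backbone[300:]
        shorter = backbone[:300] + "AAAAA" + backbone[300:]
        cluster = _cluster_of([with_run] * 80 + [shorter] * 80)
        children = split_once(cluster, RadConfig(), _stats())
        assert len(children) == 1

    def test_singleton_not_splittable(self, backbone):
        cluster = _cluster_of([backbone])
        assert split_once(cluster, RadConfig(), _stats()) == [cluster]


class TestRefine:
    def test_four_close_variants_recovered(self, backbone):
        t1 = backbone
        t2 = substitute(backbone, 200)
        t3 = substitute(backbone, 500)
        t4 = substitute(substitute(backbone, 200), 500)
        members = [t1] * 60 + [t2] * 60 + [t3] * 60 + [t4] * 60
        clusters = refine([_cluster_of(members)], RadConfig(), _stats())
        assert len(clusters) == 4
        for c in clusters:
            seqs = {members[i] for i in c.member_indices}
            assert len(seqs) == 1

    def test_partition_conserved_and_never_merges(self, backbone):
        members = [backbone] * 50 + [substitute(backbone, 100)] * 50
        initial = [_cluster_of(members)]
        refined = refine(initial, RadConfig(), _stats())
        assert len(refined) >= len(initial)
        all_indices = np.concatenate([c.member_indices for c in refined])
        assert sorted(all_indices.tolist()) == list(range(len(members)))

    def test_idempotent_on_refined_clusters(self, backbone):
        members = [backbone] * 50 + [substitute(backbone, 100)] * 50
        once = refine([_cluster_of(members)], RadConfig(), _stats())
        again = refine(once, RadConfig(), _stats())
        assert [sorted(c.member_indices.tolist()) for c in again] == [
            sorted(c.member_indices.tolist()) for c in once
        ]

    def test_max_depth_zero_returns_input(self, backbone):
        members = [backbone] * 30 + [substitute(backbone, 100)] * 30
        cluster = _cluster_of(members)
        out = refine([cluster], RadConfig(max_depth=0), _stats())
        assert out == [cluster]


class TestRadDenoise:
    def test_zero_noise_exact_recovery(self):
        pop = generate_templates(default_seed_sequence(900), 5, 8, 2, 3, 19)
        pop = WeightedPopulation(list(pop.sequences), np.full(5, 0.2))
        origins = np.repeat(np.arange(5), 12)
        reads, _ = simulate_reads(pop, 60, ZERO_NOISE, 7, origins=origins)
        result = rad_denoise(reads)
        assert set(result.sequences) == set(pop.sequences)
        assert result.frequencies == pytest.approx(np.full(5, 0.2))

    def test_noise_free_agrees_with_fad(self):
        pop = generate_templates(default_seed_sequence(700), 4, 6, 1, 2, 23)
        pop = WeightedPopulation(list(pop.sequences), np.full(4, 0.25))
        origins = np.repeat(np.arange(4), 10)
        reads, _ = simulate_reads(pop, 40, ZERO_NOISE, 11, origins=origins)
        assert set(rad_denoise(reads).sequences) == set(fad_denoise(reads).sequences)

    def test_single_base_discrimination_with_noise(self):
        tmpl = default_seed_sequence(1500)
        variant = substitute(tmpl, 750)
        pop = WeightedPopulation([tmpl, variant], np.array([0.5, 0.5]))
        profile = ErrorProfile(sub_rate=1e-3, indel_base_rate=4e-3,
                               rate_spread=0.75)
        reads, _ = simulate_reads(
            pop, 600, profile, 13, origins=np.repeat([0, 1], 300)
        )
        result = rad_denoise(reads, RadConfig(min_cluster=2))
        assert {tmpl, variant} <= set(result.sequences)
        by_seq = dict(zip(result.sequences, result.frequencies))
        assert by_seq[tmpl] + by_seq[variant] > 0.9

    def test_min_cluster_reassigns_rather_than_drops(self, backbone):
        reads = [make_read(backbone, q=40, rid=f"a{i}") for i in range(20)]
        # one heavily mutated outlier read ends up as its own cluster
        rng = np.random.default_rng(3)
        outlier = list(backbone)
        for p in rng.choice(len(outlier), size=30, replace=False):
            outlier[p] = "ACGT"[rng.integers(0, 4)]
        reads.append(make_read("".join(outlier), q=20, rid="junk"))
        result = rad_denoise(reads, RadConfig(min_cluster=2))
        assert result.sequences == [backbone]
        assert int(result.counts.sum()) == len(reads)
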