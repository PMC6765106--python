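import numpy as np
import pytest
from scipy.optimize import linprog

from ampdenoise.populations import WeightedPopulation
from ampdenoise.smd import distance_matrix, edit_distance, smd, smd_relaxed

from conftest import levenshtein_dp


def _pop(seqs, freqs):
    return WeightedPopulation(sequences=list(seqs), frequencies=np.asarray(freqs))


def _random_pop(rng, n, denom):
    seqs = ["".join(rng.choice(list("ACGT"), rng.integers(8, 20))) for _ in range(n)]
    while len(set(seqs)) < n:  # resample collisions
        seqs = [
            "".join(rng.choice(list("ACGT"), rng.integers(8, 20))) for _ in range(n)
        ]
    masses = rng.multinomial(denom, np.ones(n) / n)
    while (masses == 0).any():
        masses = rng.multinomial(denom, np.ones(n) / n)
    return seqs, masses


class TestEditDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("ACGT", "ACGT", 0), ("", "ACGTA", 5), ("kitten", "sitting", 3)],
    )
    def test_examples(self, a, b, expected):
        assert edit_distance(a, b) == expected

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), rng.integers(0, 25)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(0, 25)))
            assert edit_distance(a, b) == levenshtein_dp(a, b)


class TestSmd:
    def test_identical_populations_zero(self):
        pop = _pop(["ACGTACGT", "TTTTCCCC"], [0.4, 0.6])
        res = smd(pop, pop)
        assert res.smd == pytest.approx(0.0, abs=1e-9)

    def test_singletons_forced_flow(self):
        a, b = "ACGTACGTAA", "ACGAACGTAA"
        res = smd(_pop([a], [1.0]), _pop([b], [1.0]))
        assert res.smd == pytest.approx(edit_distance(a, b))

    def test_two_by_two_closed_form(self):
        a, b = "AAAAAAA", "AAATTAA"
        d = edit_distance(a, b)
        res = smd(_pop([a, b], [0.5, 0.5]), _pop([a, b], [0.25, 0.75]))
        assert res.smd == pytest.approx(0.25 * d, abs=1e-7)

    def test_flow_marginals_and_objective(self):
        rng = np.random.default_rng(3)
        t_seqs, t_mass = _random_pop(rng, 4, 40)
        i_seqs, i_mass = _random_pop(rng, 5, 40)
        truth = _pop(t_seqs, t_mass / 40)
        inferred = _pop(i_seqs, i_mass / 40)
        res = smd(truth, inferred)
        assert res.F.min() >= -1e-9
        assert res.F.sum(axis=1) == pytest.approx(truth.frequencies, abs=1e-7)
        assert res.F.sum(axis=0) == pytest.approx(inferred.frequencies, abs=1e-7)
        assert res.smd == pytest.approx(float((res.F * res.D).sum()), abs=1e-7)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        t_seqs, t_mass = _random_pop(rng, 3, 30)
        i_seqs, i_mass = _random_pop(rng, 4, 30)
        a = _pop(t_seqs, t_mass / 30)
        b = _pop(i_seqs, i_mass / 30)
        assert smd(a, b).smd == pytest.approx(smd(b, a).smd, abs=1e-7)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            _pop(["AAAA", "CCCC"], [0.5, 0.6])

    def test_network_simplex_oracle(self):
        """LP optimum equals an independent min-cost-flow solution."""
        networkx = pytest.importorskip("networkx")
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, m = rng.integers(2, 7), rng.integers(2, 7)
            denom = 60
            t_seqs, t_mass = _random_pop(rng, n, denom)
            i_seqs, i_mass = _random_pop(rng, m, denom)
            truth = _pop(t_seqs, t_mass / denom)
            inferred = _pop(i_seqs, i_mass / denom)
            D = distance_matrix(truth, inferred).astype(int)
            G = networkx.DiGraph()
            for i in range(n):
                G.add_node(("t", i), demand=-int(t_mass[i]))
            for j in range(m):
                G.add_node(("i", j), demand=int(i_mass[j]))
            for i in range(n):
                for j in range(m):
                    G.add_edge(("t", i), ("i", j), weight=int(D[i, j]))
            cost = networkx.cost_of_flow(G, networkx.min_cost_flow(G))
            res = smd(truth, inferred)
            assert res.smd == pytest.approx(cost / denom, abs=1e-7)


class TestRelaxed:
    def test_inferred_subset_of_truth_no_false_positives(self):
        truth = _pop(["AAAAAAA", "CCCCCCC", "GGGGGGG"], [0.2, 0.3, 0.5])
        inferred = _pop(["CCCCCCC", "AAAAAAA"], [0.9, 0.1])
        fp, fn = smd_relaxed(truth, inferred)
        assert fp == pytest.approx(0.0)
        assert fn > 0

    def test_truth_subset_of_inferred_no_false_negatives(self):
        truth = _pop(["AAAAAAA"], [1.0])
        inferred = _pop(["AAAAAAA", "TTTTTTT"], [0.5, 0.5])
        fp, fn = smd_relaxed(truth, inferred)
        assert fn == pytest.approx(0.0)
        assert fp > 0

    def test_closed_form_matches_single_marginal_lp(self):
        rng = np.random.default_rng(9)
        t_seqs, t_mass = _random_pop(rng, 3, 30)
        i_seqs, i_mass = _random_pop(rng, 3, 30)
        truth = _pop(t_seqs, t_mass / 30)
        inferred = _pop(i_seqs, i_mass / 30)
        D = distance_matrix(truth, inferred)
        n, m = D.shape
        # SMD_FP: only the column (inferred) marginal is constrained.
        A_eq = np.zeros((m, n * m))
        for j in range(m):
            A_eq[j, j::m] = 1.0
        lp = linprog(D.ravel(), A_eq=A_eq, b_eq=inferred.frequencies,
                     bounds=(0, None), method="highs")
        fp, fn = smd_relaxed(truth, inferred)
        assert fp == pytest.approx(lp.fun, abs=1e-7)
        # SMD_FN symmetrically via transposition.
        A_eq2 = np.zeros((n, n * m))
        for i in range(n):
            A_eq2[i, i * m : (i + 1) * m] = 1.0
        lp2 = linprog(D.ravel(), A_eq=A_eq2, b_eq=truth.frequencies,
                      bounds=(0, None), method="highs")
        assert fn == pytest.approx(lp2.fun, abs=1e-7)

    def test_relaxed_bounded_by_full_smd(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            t_seqs, t_mass = _random_pop(rng, 4, 40)
            i_seqs, i_mass = _random_pop(rng, 4, 40)
            truth = _pop(t_seqs, t_mass / 40)
            inferred = _pop(i_seqs, i_mass / 40)
            res = smd(truth, inferred)
            assert max(res.smd_fp, res.smd_fn) <= res.smd + 1e-7
            assert res.smd <= res.D.max() + 1e-9
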