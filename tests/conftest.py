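"""Shared test helpers: read builders, oracle implementations, sequences."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from ampdenoise.seq_io import Read

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = "ACGT"
_NEXT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def make_read(sequence: str, q: int = 40, rid: str = "r") -> Read:
    return Read(
        id=rid,
        sequence=sequence,
        quality=np.full(len(sequence), q, dtype=np.int16),
    )


def substitute(sequence: str, pos: int) -> str:
    """Deterministic single substitution at ``pos``."""
    return sequence[:pos] + _NEXT[sequence[pos]] + sequence[pos + 1 :]


def unique_kmer_sequence(length: int, k: int = 6, seed: int = 3) -> str:
    """A sequence in which every k-window occurs exactly once.

    Greedy randomized construction with full restarts; deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    while True:
        seq: list[str] = []
        used: set[str] = set()
        ok = True
        for i in range(length):
            placed = False
            for b in rng.permutation(4):
                cand = seq + [BASES[b]]
                if i >= k - 1:
                    kmer = "".join(cand[i - k + 1 : i + 1])
                    if kmer in used:
                        continue
                    used.add(kmer)
                seq = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return "".join(seq)


def poisson_tail(n: int, mu: float) -> float:
    """P(X >= n) for X ~ Poisson(mu), by direct summation of the pmf."""
    if n <= 0:
        return 1.0
    total = 0.0
    term = math.exp(-mu)
    for k in range(n):
        total += term
        term *= mu / (k + 1)
    return max(0.0, 1.0 - total)


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook O(nm) edit-distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)
            )
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def unique_1000mer() -> str:
    return unique_kmer_sequence(1000, seed=3)
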