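"""Kmer count vectors and the corrected kmer approximation of edit distance.

Sequences are represented as integer count vectors over all ``4**k`` kmers
(2-bit encoding, A=0, C=1, G=2, T=3, big-endian within the kmer). For two
such vectors ``A`` and ``B`` the corrected distance

    D(A, B) = (1 / 2k) * sum_i (A_i - B_i)**2

approximates the pairwise edit distance: a single substitution in a
non-repetitive context changes ``k`` windows, i.e. ``2k`` count entries by
±1, contributing exactly 1 to D. Indels — in particular homopolymer
length changes, the dominant CCS error mode — perturb far fewer counts and
are therefore down-weighted, which is the desired behaviour when the error
process is indel-dominated.

This module also provides the helpers used by cluster refinement: selection
of high-variance kmer coordinates and detection of kmer pairs related by a
single homopolymer length edit.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

DEFAULT_K = 6

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

# Byte-indexed lookup: ACGT -> 0..3, everything else (incl. N) -> -1.
_CODE_TABLE = np.full(256, -1, dtype=np.int64)
for _b, _c in _BASE_CODE.items():
    _CODE_TABLE[ord(_b)] = _c
    _CODE_TABLE[ord(_b.lower())] = _c


@dataclass(frozen=True)
class KmerVector:
    """Integer kmer count vector of length ``4**k``.

    Attributes
    ----------
    counts:
        Counts per kmer in canonical order (A<C<G<T, lexicographic).
    k:
        Kmer length.
    seq_length:
        Length of the originating sequence (used by :func:`scaled_distance`).
    """

    counts: np.ndarray
    k: int
    seq_length: int


def encode_sequence(sequence: str) -> np.ndarray:
    """2-bit encode a DNA string; non-ACGT characters become -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def kmer_index(kmer: str) -> int:
    """Canonical index of a kmer (big-endian 2-bit encoding)."""
    idx = 0
    for base in kmer:
        idx = (idx << 2) | _BASE_CODE[base]
    return idx


def index_to_kmer(index: int, k: int) -> str:
    """Inverse of :func:`kmer_index`."""
    chars = []
    for _ in range(k):
        chars.append(_CODE_BASE[index & 3])
        index >>= 2
    return "".join(reversed(chars))


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Indices of all length-k windows; windows containing N yield -1."""
    n = codes.size - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = windows @ powers
    bad = (windows < 0).any(axis=1)
    vals = np.where(bad, -1, vals)
    return vals[:n]


def kmer_vector(sequence: str, k: int = DEFAULT_K) -> KmerVector:
    """Count every length-k window of ``sequence``; windows with N are skipped.

    Raises
    ------
    ValueError
        If ``sequence`` is shorter than ``k`` or ``k < 1``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    vals = _window_codes(encode_sequence(sequence), k)
    vals = vals[vals >= 0]
    counts = np.bincount(vals, minlength=4**k).astype(np.int32)
    return KmerVector(counts=counts, k=k, seq_length=len(sequence))


def kmer_matrix(sequences: list[str], k: int = DEFAULT_K) -> np.ndarray:
    """Stacked kmer counts, one row per sequence (shape ``(n, 4**k)``)."""
    out = np.zeros((len(sequences), 4**k), dtype=np.int32)
    for i, seq in enumerate(sequences):
        out[i] = kmer_vector(seq, k).counts
    return out


def _check_compatible(u: KmerVector, v: KmerVector) -> None:
    if u.k != v.k:
        raise ValueError(f"kmer lengths differ: {u.k} != {v.k}")


def corrected_distance(u: KmerVector, v: KmerVector) -> float:
    """Corrected kmer distance, in base-equivalent units.

    ``(1/2k) * sum((u_i - v_i)**2)``: approximately the number of
    substitutions separating the two sequences at low divergence.
    """
    _check_compatible(u, v)
    diff = u.counts.astype(np.int64) - v.counts.astype(np.int64)
    return float(np.dot(diff, diff)) / (2.0 * u.k)


def scaled_distance(u: KmerVector, v: KmerVector) -> float:
    """Corrected distance divided by the mean sequence length.

    Yields a per-base divergence fraction, comparable to an expected error
    rate. The mean of the two lengths keeps the operation symmetric for
    unequal-length sequences.
    """
    mean_len = 0.5 * (u.seq_length + v.seq_length)
    return corrected_distance(u, v) / mean_len


def euclidean_kmer_distance(u: KmerVector, v: KmerVector) -> float:
    """Plain Euclidean distance between count vectors.

    Unlike the corrected distance (a squared quantity), this is a true
    metric and satisfies the triangle inequality, which is what makes
    exact distance pruning possible. ``corrected == euclidean**2 / (2k)``.
    """
    _check_compatible(u, v)
    diff = u.counts.astype(np.int64) - v.counts.astype(np.int64)
    return float(np.sqrt(np.dot(diff, diff)))


def homopolymer_length_edit_pair(a: str, b: str) -> bool:
    """True iff kmers ``a`` and ``b`` differ by a single homopolymer length edit.

    Constructively: deleting one character of ``a`` that sits in a run
    (equal to an adjacent character) must yield a (k-1)-mer that is a prefix
    or suffix of ``b``, or symmetrically with the roles swapped. Identical
    kmers are not a pair.
    """
    if len(a) != len(b):
        raise ValueError("kmers must have equal length")
    if a == b:
        return False
    for x, y in ((a, b), (b, a)):
        n = len(x)
        for i in range(n):
            in_run = (i > 0 and x[i] == x[i - 1]) or (
                i < n - 1 and x[i] == x[i + 1]
            )
            if not in_run:
                continue
            shortened = x[:i] + x[i + 1 :]
            if y.startswith(shortened) or y.endswith(shortened):
                return True
    return False


@lru_cache(maxsize=65536)
def _edit_pair_partners(kmer: str) -> tuple[str, ...]:
    """All kmers forming a homopolymer length-edit pair with ``kmer``.

    Constructive enumeration: delete each run character and re-extend at
    either end, or re-insert a character into the two (k-1)-prefixes/
    suffixes; candidates are verified with the pair predicate. The set is
    small (tens), so partners can be checked exhaustively instead of
    hoping both members of a pair surface in a variance ranking.
    """
    k = len(kmer)
    candidates: set[str] = set()
    for i in range(k):
        in_run = (i > 0 and kmer[i] == kmer[i - 1]) or (
            i < k - 1 and kmer[i] == kmer[i + 1]
        )
        if not in_run:
            continue
        core = kmer[:i] + kmer[i + 1 :]
        for b in "ACGT":
            candidates.add(core + b)
            candidates.add(b + core)
    for stem in (kmer[:-1], kmer[1:]):
        for j in range(len(stem) + 1):
            for b in "ACGT":
                candidates.add(stem[:j] + b + stem[j:])
    candidates.discard(kmer)
    return tuple(
        y for y in sorted(candidates) if homopolymer_length_edit_pair(kmer, y)
    )


def top_variance_kmers(
    counts: np.ndarray,
    k: int = DEFAULT_K,
    m_pool: int = 20,
    n_keep: int = 6,
) -> list[int]:
    """Select up to ``n_keep`` high-variance kmer coordinates for splitting.

    From a matrix of kmer counts (rows = reads), take the ``m_pool`` indices
    with the largest population variance (ties broken toward the lower
    index), discard every index participating in a homopolymer length-edit
    pair within that pool, and return the ``n_keep`` highest-variance
    survivors. Fewer than ``n_keep`` survivors are returned as-is.

    The homopolymer exclusion prevents cluster splitting from keying on the
    dominant (and heavily shared) homopolymer indel errors. A pair counts
    only when the two coordinates actually trade counts across reads
    (negative covariance): a real ±1 homopolymer edit replaces one kmer by
    the other, so their counts anticorrelate, whereas consecutive windows
    of one and the same haplotype — which are string-wise indistinguishable
    from an edit pair — co-vary positively and must not be discarded.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a (n >= 2) x 4**k count matrix")
    if not (m_pool >= n_keep >= 1):
        raise ValueError("require m_pool >= n_keep >= 1")
    variances = counts.var(axis=0).astype(float)  # population variance
    # Multi-copy kmers (several loci feeding one coordinate) aggregate
    # noise from every locus they touch, inflating their variance while
    # diluting genuine between-variant signal; pure homopolymer kmers
    # count nothing but run length, the dominant error mode. Neither is
    # selectable (both remain visible as pair partners below).
    selectable = variances.copy()
    selectable[counts.mean(axis=0) > 1.5] = -1.0
    for base in "ACGT":
        selectable[kmer_index(base * k)] = -1.0
    # Stable selection: largest variance first, ties by lower index.
    order = np.lexsort((np.arange(selectable.size), -selectable))
    pool = [int(i) for i in order[:m_pool]]
    # A candidate is discarded when any of its possible edit partners
    # anticorrelates with it across reads: counts flowing from one kmer of
    # the pair to the other is the data signature of a homopolymer length
    # edit. Genuine trades are near-perfectly anticorrelated (every loss
    # of one kmer is a gain of the other), so Pearson correlation is the
    # right scale: partners gained through unrelated noise — even noise
    # that happens to correlate with haplotype structure — sit near zero,
    # and consecutive windows of one and the same haplotype, which
    # satisfy the identical string relation, correlate positively.
    centered = counts.astype(float) - counts.mean(axis=0)
    n_reads = counts.shape[0]
    discarded: set[int] = set()
    for i in pool:
        if variances[i] <= 0.0:
            continue
        for partner in _edit_pair_partners(index_to_kmer(i, k)):
            j = kmer_index(partner)
            if variances[j] <= 0.0:
                continue
            corr = float(centered[:, i] @ centered[:, j]) / (
                n_reads * np.sqrt(variances[i] * variances[j])
            )
            if corr < -0.35:
                discarded.add(i)
                break
    survivors = [i for i in pool if i not in discarded]
    return survivors[:n_keep]
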