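"""Cluster consensus: draft selection, kmer-seeded alignment, modal polishing.

Clusters produced in the high-noise regime rarely contain a noise-free
read, so the template is inferred by averaging. The member read whose kmer
vector lies nearest the cluster mean vector serves as a draft. Every
member is then aligned to the draft using long (default 30-mer) anchor
seeds that are unique in both sequences, chained by a longest increasing
subsequence, with the short unanchored stretches filled in by exact
edit-distance alignment — an approximate pairwise alignment that scales
linearly with sequence length. Finally the draft is scanned in
fixed-width blocks: wherever the reads' modal aligned subsequence (strict
plurality) disagrees with the draft block, the draft is rewritten to the
modal value, and the sweep repeats (re-aligning) until a fixed point or a
round cap.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import edlib
import numpy as np

from .kmers import encode_sequence, kmer_matrix

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XMIDS])")


@dataclass
class ConsensusConfig:
    """Anchor kmer length, polishing block width and iteration cap."""

    seed_k: int = 30
    window: int = 15
    max_rounds: int = 3

    def __post_init__(self) -> None:
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


@dataclass
class PairwiseAlignment:
    """Monotone draft-to-read coordinate mapping with its edit cost.

    ``draft_to_read[i]`` is the read coordinate aligned to draft boundary
    ``i`` (0..len(draft)), non-decreasing; the read subsequence aligned to
    draft span [s, e) is ``read[draft_to_read[s]:draft_to_read[e]]``.
    """

    draft_to_read: np.ndarray
    score: int


def _window_values(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-windows (-1 where the window contains N)."""
    codes = encode_sequence(seq)
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = windows @ powers
    return np.where((windows < 0).any(axis=1), -1, vals)


def _unique_kmer_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(sorted codes, positions) of kmers occurring exactly once."""
    vals = _window_values(seq, k)
    codes, first, counts = np.unique(vals, return_index=True, return_counts=True)
    keep = (counts == 1) & (codes >= 0)
    return codes[keep], first[keep]


def _chain_anchors(dpos: np.ndarray, rpos: np.ndarray) -> list[int]:
    """Longest increasing subsequence of rpos over dpos-sorted anchors."""
    import bisect

    tails: list[int] = []  # rpos values
    tails_idx: list[int] = []
    parent = np.full(dpos.size, -1, dtype=int)
    for i in range(dpos.size):
        pos = bisect.bisect_left(tails, rpos[i])
        if pos == len(tails):
            tails.append(int(rpos[i]))
            tails_idx.append(i)
        else:
            tails[pos] = int(rpos[i])
            tails_idx[pos] = i
        parent[i] = tails_idx[pos - 1] if pos > 0 else -1
    chain: list[int] = []
    cur = tails_idx[-1] if tails_idx else -1
    while cur >= 0:
        chain.append(cur)
        cur = parent[cur]
    chain.reverse()
    return chain


def _edlib_segment(map_: np.ndarray, dseg: str, rseg: str, d: int, r: int) -> int:
    """Globally align a draft segment to a read segment, extending ``map_``.

    Returns the segment's edit cost. ``d``/``r`` are the absolute start
    coordinates of the segments.
    """
    if not dseg and not rseg:
        return 0
    if not dseg:
        return len(rseg)  # pure read insertion: map stays flat at boundary
    if not rseg:
        map_[d + 1 : d + len(dseg) + 1] = r
        return len(dseg)
    res = edlib.align(dseg, rseg, mode="NW", task="path")
    dd, rr = d, r
    for count_s, op in _CIGAR_RE.findall(res["cigar"]):
        count = int(count_s)
        if op in "=XM":
            map_[dd + 1 : dd + count + 1] = np.arange(rr + 1, rr + count + 1)
            dd += count
            rr += count
        elif op == "I":  # consumes draft only (deletion in read)
            map_[dd + 1 : dd + count + 1] = rr
            dd += count
        elif op == "D":  # consumes read only (insertion in read)
            rr += count
    return int(res["editDistance"])


class _DraftIndex:
    """Reusable per-draft state for aligning many reads to one draft."""

    def __init__(self, draft: str, seed_k: int):
        self.draft = draft
        self.seed_k = seed_k
        self.codes, self.positions = _unique_kmer_positions(draft, seed_k)

    def align(self, read: str) -> PairwiseAlignment:
        draft, k = self.draft, self.seed_k
        map_ = np.zeros(len(draft) + 1, dtype=np.int64)
        r_codes, r_pos = _unique_kmer_positions(read, k)
        if self.codes.size and r_codes.size:
            loc = np.minimum(
                np.searchsorted(self.codes, r_codes), self.codes.size - 1
            )
            shared = self.codes[loc] == r_codes
            dpos = self.positions[loc[shared]]
            rpos = r_pos[shared]
        else:
            dpos = np.empty(0, dtype=np.int64)
            rpos = np.empty(0, dtype=np.int64)
        order = np.argsort(dpos, kind="stable")
        dpos, rpos = dpos[order], rpos[order]

        if dpos.size == 0:
            logger.debug("no unique anchors; falling back to full alignment")
            score = _edlib_segment(map_, draft, read, 0, 0)
            map_[len(draft)] = len(read)
            return PairwiseAlignment(draft_to_read=map_, score=score)

        chain = _chain_anchors(dpos, rpos)
        # Merge chained anchors into exact blocks [d0,d1) ~ [r0,r1); anchors
        # on the same diagonal that overlap or touch extend the block, since
        # the union of overlapping verified kmers is itself verified.
        blocks: list[list[int]] = []
        for ci in chain:
            d, r = int(dpos[ci]), int(rpos[ci])
            if blocks:
                d0, d1, r0, r1 = blocks[-1]
                if d - r == d1 - r1 and d <= d1:
                    blocks[-1][1] = max(d1, d + k)
                    blocks[-1][3] = max(r1, r + k)
                    continue
                if d < d1 or r < r1:
                    # Crossing overlap with the previous block: skip anchor.
                    continue
            blocks.append([d, d + k, r, r + k])

        score = 0
        prev_d, prev_r = 0, 0
        for d0, d1, r0, r1 in blocks:
            score += _edlib_segment(
                map_, draft[prev_d:d0], read[prev_r:r0], prev_d, prev_r
            )
            map_[d0 + 1 : d1 + 1] = np.arange(r0 + 1, r1 + 1)
            prev_d, prev_r = d1, r1
        score += _edlib_segment(
            map_, draft[prev_d:], read[prev_r:], prev_d, prev_r
        )
        # Trailing read bases (a read-only cigar tail) would otherwise be
        # invisible to the last polishing block, making it impossible for
        # voting to restore a truncated draft end.
        map_[len(draft)] = len(read)
        return PairwiseAlignment(draft_to_read=map_, score=score)


def seeded_align(
    read: str, draft: str, config: ConsensusConfig | None = None
) -> PairwiseAlignment:
    """Anchor-seeded approximate pairwise alignment of ``read`` to ``draft``.

    Anchors are ``seed_k``-mers unique within both sequences, chained by a
    longest increasing subsequence; unanchored stretches are aligned by
    exact edit distance. With zero anchors the full exact alignment is used.
    """
    config = config or ConsensusConfig()
    if len(read) < config.seed_k or len(draft) < config.seed_k:
        raise ValueError("sequences must be at least seed_k long")
    return _DraftIndex(draft, config.seed_k).align(read)


def _polish_round(
    draft: str, reads: list[str], index: _DraftIndex, window: int
) -> str:
    """One sweep of modal block replacement over the draft."""
    alignments = [index.align(read) for read in reads]
    out: list[str] = []
    for start in range(0, len(draft), window):
        end = min(start + window, len(draft))
        draft_block = draft[start:end]
        votes: dict[str, int] = {}
        for aln, read in zip(alignments, reads):
            sub = read[aln.draft_to_read[start] : aln.draft_to_read[end]]
            votes[sub] = votes.get(sub, 0) + 1
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])
        if ranked and (len(ranked) == 1 or ranked[0][1] > ranked[1][1]):
            out.append(ranked[0][0])  # strict plurality wins
        else:
            out.append(draft_block)  # tie: keep the draft
    return "".join(out)


def polish(
    draft: str, reads: list[str], config: ConsensusConfig | None = None
) -> str:
    """Iteratively replace draft blocks by the reads' modal subsequence.

    Re-aligns after every changed round (so indel corrections propagate)
    until a fixed point or ``max_rounds`` sweeps.
    """
    config = config or ConsensusConfig()
    if not reads:
        raise ValueError("polish needs at least one aligned read")
    for _ in range(config.max_rounds):
        index = _DraftIndex(draft, config.seed_k)
        new_draft = _polish_round(draft, reads, index, config.window)
        if new_draft == draft:
            break
        draft = new_draft
    return draft


def draft_consensus(
    sequences: list[str], counts: np.ndarray | None = None, k: int = 6
) -> str:
    """Member sequence whose kmer vector is nearest the cluster mean vector.

    Ties break to the lowest member index. ``counts`` may supply
    precomputed kmer vectors (rows matching ``sequences``).
    """
    if not sequences:
        raise ValueError("cluster is empty")
    if counts is None:
        counts = kmer_matrix(sequences, k)
    mean = counts.mean(axis=0)
    diff = counts - mean
    dist = np.einsum("ij,ij->i", diff, diff)
    return sequences[int(np.argmin(dist))]


def cluster_consensus(
    sequences: list[str],
    counts: np.ndarray | None = None,
    config: ConsensusConfig | None = None,
    k: int = 6,
) -> str:
    """Draft selection followed by modal polishing for one cluster."""
    config = config or ConsensusConfig()
    draft = draft_consensus(sequences, counts=counts, k=k)
    if len(sequences) == 1:
        return draft
    usable = [s for s in sequences if len(s) >= config.seed_k]
    if not usable:
        return draft
    return polish(draft, usable, config)
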