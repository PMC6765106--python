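"""Fast Amplicon Denoising (FAD): read-selection denoising for the
short-and-accurate regime.

When an appreciable fraction of reads carries zero errors, the true
templates are literally present in the data as repeated identical reads.
FAD dereplicates, walks the unique sequences from most to least abundant,
and keeps a candidate when either (a) it is more than one base-equivalent
of corrected kmer distance away from every already-accepted template, or
(b) it is too abundant to be explained as a one-base error copy of its
most abundant accepted neighbour, judged by a Bonferroni-corrected Poisson
tail test at level alpha. Every input read is finally assigned to its
nearest accepted template to produce counts and frequencies.

FAD never averages reads: accepted templates are verbatim input sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from . import seq_io
from .kmers import DEFAULT_K, kmer_matrix
from .populations import TemplateSet
from .seq_io import Read, dereplicate, prob_error_free

logger = logging.getLogger(__name__)

# Below this estimated error-free fraction, read selection is starved of
# noiseless reads and cluster-and-average denoising should be used instead.
LOW_ERROR_FREE_WARNING = 0.05


class FadRegimeError(RuntimeError):
    """No usable candidates: the data is outside FAD's operating regime."""


@dataclass
class FadConfig:
    """Significance level, abundance floor and neighbourhood radius."""

    alpha: float = 0.01
    min_count: int = 2
    neighbor_radius: float = 1.0
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def error_free_fraction(reads: list[Read]) -> float:
    """Mean over reads of exp(-expected_errors): the expected proportion of
    error-free sequences in the dataset."""
    if not reads:
        raise ValueError("error_free_fraction needs at least one read")
    return float(np.mean([prob_error_free(r.expected_errors) for r in reads]))


def offspring_pvalue(
    parent_count: float,
    offspring_count: int,
    f0: float,
    mean_errors: float,
    mean_length: float,
) -> float:
    """P-value for an offspring abundance under the one-base-error null.

    The null: the offspring is a pile of reads of the parent template that
    all suffered an error at the same single site. The observed parent
    abundance is corrected up to total molecules by the error-free
    fraction ``f0``; errors are taken as uniform over sites, so the
    expected number of error copies at one specific site is

        mu = (parent_count / f0) * mean_errors / mean_length

    The raw upper tail P(X >= offspring_count), X ~ Poisson(mu), is
    Bonferroni-corrected for the number of sites (capped at 1). A small
    p-value means the offspring is too large to be an error artifact.
    """
    if not (0 < f0 <= 1):
        raise ValueError("f0 must be in (0, 1]")
    if mean_length <= 0:
        raise ValueError("mean_length must be > 0")
    mu = (parent_count / f0) * mean_errors / mean_length
    raw = float(poisson.sf(offspring_count - 1, mu)) if mu > 0 else float(
        offspring_count == 0
    )
    return min(1.0, mean_length * raw)


def assign_to_templates(
    reads: list[Read],
    templates: list[str],
    template_counts=None,
    k: int = DEFAULT_K,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each read to its nearest template under corrected kmer distance.

    Ties go to the template with the larger pre-assignment count
    (``template_counts``), then to the lower template index. Returns
    (counts, frequencies) over templates.
    """
    if not templates:
        raise ValueError("need at least one template")
    if template_counts is None:
        template_counts = np.zeros(len(templates))
    template_counts = np.asarray(template_counts)
    read_k = kmer_matrix([r.sequence for r in reads], k).astype(np.float64)
    tmpl_k = kmer_matrix(templates, k).astype(np.float64)
    # Squared Euclidean cross-distances; the 1/(2k) factor is monotone and
    # irrelevant for argmin.
    sq = (
        (read_k**2).sum(axis=1)[:, None]
        - 2.0 * read_k @ tmpl_k.T
        + (tmpl_k**2).sum(axis=1)[None, :]
    )
    # Tie rule: scan templates in (count desc, index asc) priority order so
    # argmin's first-minimum behaviour implements it.
    priority = np.lexsort((np.arange(len(templates)), -template_counts))
    choice = priority[np.argmin(sq[:, priority], axis=1)]
    counts = np.bincount(choice, minlength=len(templates))
    return counts, counts / max(len(reads), 1)


def fad_denoise(reads: list[Read], config: FadConfig | None = None) -> TemplateSet:
    """Run FAD on quality-filtered reads.

    Raises :class:`FadRegimeError` when no dereplicated sequence reaches
    ``min_count`` — the hallmark of data without error-free duplicates,
    where RAD should be used instead.
    """
    config = config or FadConfig()
    if not reads:
        raise ValueError("fad_denoise needs at least one read")
    table = dereplicate(reads)
    candidates = [(s, c) for s, c in table.entries if c >= config.min_count]
    f0 = error_free_fraction(reads)
    dup_frac = seq_io.duplicate_fraction(reads)
    if f0 < LOW_ERROR_FREE_WARNING:
        logger.warning(
            "estimated error-free fraction %.4f is very low; "
            "read selection is unlikely to see the true templates -- "
            "consider RAD (cluster-and-consensus) instead",
            f0,
        )
    logger.info(
        "fad diagnostics error_free_fraction=%.4f duplicate_fraction=%.4f",
        f0,
        dup_frac,
    )
    if not candidates:
        raise FadRegimeError(
            "no sequence occurs at least "
            f"{config.min_count} times; there are too few error-free reads "
            "for read-selection denoising -- use RAD instead"
        )
    mean_errors = float(np.mean([r.expected_errors for r in reads]))
    mean_length = float(np.mean([len(r) for r in reads]))

    cand_k = kmer_matrix([s for s, _ in candidates], config.k).astype(np.float64)
    accepted: list[int] = []  # candidate indices, in acceptance order
    for idx, (_, count) in enumerate(candidates):
        if not accepted:
            accepted.append(idx)
            continue
        acc_k = cand_k[accepted]
        diff = acc_k - cand_k[idx]
        dist = np.einsum("ij,ij->i", diff, diff) / (2.0 * config.k)
        neighbors = np.flatnonzero(dist <= config.neighbor_radius)
        if neighbors.size == 0:
            accepted.append(idx)
            continue
        # Most abundant accepted template within the radius; candidates are
        # processed in abundance order so the earliest neighbour is it.
        parent_idx = accepted[int(neighbors[0])]
        parent_count = candidates[parent_idx][1]
        p = offspring_pvalue(parent_count, count, f0, mean_errors, mean_length)
        if p <= config.alpha:
            accepted.append(idx)

    sequences = [candidates[i][0] for i in accepted]
    pre_counts = [candidates[i][1] for i in accepted]
    counts, frequencies = assign_to_templates(
        reads, sequences, template_counts=pre_counts, k=config.k
    )
    return TemplateSet(sequences=sequences, counts=counts, frequencies=frequencies)
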