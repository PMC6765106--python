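"""Sequence I/O, quality-derived error statistics, filtering and dereplication.

Reads come in as Phred+33 FASTQ. Per-base quality scores are converted to
error probabilities ``p_i = 10**(-Q_i/10)`` and summed into an expected
number of errors per read — the quantity that drives quality filtering, the
error-free-fraction estimate and the Poisson abundance test downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .populations import TemplateSet, WeightedPopulation

PHRED_OFFSET = 33


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records (e.g. seq/quality length mismatch)."""


@dataclass
class Read:
    """A single CCS read with Phred qualities and derived expected errors."""

    id: str
    sequence: str
    quality: np.ndarray
    expected_errors: float = field(init=False)

    def __post_init__(self) -> None:
        self.quality = np.asarray(self.quality, dtype=np.int16)
        if self.quality.size != len(self.sequence):
            raise FastqFormatError(
                f"record {self.id!r}: quality length {self.quality.size} "
                f"!= sequence length {len(self.sequence)}"
            )
        self.expected_errors = expected_errors(self.quality)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def error_rate(self) -> float:
        """Expected errors per base."""
        return self.expected_errors / len(self.sequence)


def expected_errors(quality) -> float:
    """Sum of Phred-derived per-base error probabilities, sum_i 10^(-Q_i/10)."""
    q = np.asarray(quality, dtype=float)
    if q.size == 0:
        return 0.0
    if (q < 0).any():
        raise ValueError("Phred scores must be >= 0")
    return float(np.sum(10.0 ** (-q / 10.0)))


def prob_error_free(exp_errors: float) -> float:
    """Probability of zero errors under a Poisson error count, exp(-E).

    The Poisson form (rather than the exact product of per-base
    probabilities) matches the error model used by the abundance
    significance test; the two agree to second order in the per-base rates.
    """
    if exp_errors < 0:
        raise ValueError("expected errors must be >= 0")
    return math.exp(-exp_errors)


def read_fastq(path: str | PathLike) -> list[Read]:
    """Parse a Phred+33 FASTQ file into Reads, in file order.

    An empty file yields an empty list. A record whose quality string does
    not match its sequence length raises :class:`FastqFormatError` naming
    the record.
    """
    reads: list[Read] = []
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                rid = title.split(None, 1)[0] if title else ""
                quality = (
                    np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                        np.int16
                    )
                    - PHRED_OFFSET
                )
                if quality.size != len(seq):
                    raise FastqFormatError(
                        f"record {rid!r}: quality length {quality.size} "
                        f"!= sequence length {len(seq)}"
                    )
                reads.append(Read(id=rid, sequence=seq.upper(), quality=quality))
        except ValueError as exc:
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(str(exc)) from exc
    return reads


def write_fastq(reads: list[Read], path: str | PathLike) -> None:
    """Write reads as 4-line-per-record Phred+33 FASTQ."""
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(int(q) + PHRED_OFFSET) for q in read.quality)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def filter_by_error_rate(reads: list[Read], max_rate: float) -> list[Read]:
    """Keep reads whose expected error rate per base is <= ``max_rate``."""
    if not (0 < max_rate <= 1):
        raise ValueError("max_rate must be in (0, 1]")
    return [r for r in reads if r.error_rate <= max_rate]


@dataclass
class DerepTable:
    """Dereplicated reads: unique sequences with abundances.

    Entries are ordered by count descending, ties broken lexicographically
    by sequence, so iteration order is deterministic.
    """

    entries: list[tuple[str, int]]

    @property
    def sequences(self) -> list[str]:
        return [seq for seq, _ in self.entries]

    @property
    def counts(self) -> list[int]:
        return [count for _, count in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def dereplicate(reads: list[Read]) -> DerepTable:
    """Collapse exact full-length sequence duplicates into (sequence, count)."""
    tally: dict[str, int] = {}
    for read in reads:
        tally[read.sequence] = tally.get(read.sequence, 0) + 1
    entries = sorted(tally.items(), key=lambda item: (-item[1], item[0]))
    return DerepTable(entries=entries)


def duplicate_fraction(reads: list[Read]) -> float:
    """Fraction of reads whose sequence occurs at least twice.

    A regime diagnostic: read-selection denoising needs an appreciable
    number of repeated (i.e. error-free) reads.
    """
    if not reads:
        return 0.0
    table = dereplicate(reads)
    duplicated = sum(c for c in table.counts if c >= 2)
    return duplicated / len(reads)


def write_templates(
    templates: TemplateSet,
    path: str | PathLike,
    with_freq: bool = True,
) -> None:
    """Write templates as FASTA with USEARCH-style ``;size=`` annotations.

    Headers look like ``>template1;size=42;freq=0.350000``; the ``freq``
    field (6 decimal places) is optional.
    """
    with open(path, "w") as handle:
        for i, seq in enumerate(templates.sequences):
            header = f"template{i + 1};size={int(templates.counts[i])}"
            if with_freq:
                header += f";freq={templates.frequencies[i]:.6f}"
            handle.write(f">{header}\n{seq}\n")


def read_templates(path: str | PathLike) -> TemplateSet:
    """Read an annotated template FASTA back into a TemplateSet.

    Frequencies are taken from ``;freq=`` when present on every record,
    otherwise normalized from ``;size=``; absent annotations mean size 1.
    """
    names: list[str] = []
    seqs: list[str] = []
    sizes: list[int] = []
    freqs: list[float | None] = []
    current: list[str] = []

    def flush() -> None:
        if names:
            seqs.append("".join(current).upper())
            current.clear()

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                names.append(header)
                size = 1
                freq: float | None = None
                for part in header.split(";"):
                    if part.startswith("size="):
                        size = int(part[5:])
                    elif part.startswith("freq="):
                        freq = float(part[5:])
                sizes.append(size)
                freqs.append(freq)
            else:
                current.append(line)
    flush()
    if not seqs:
        return TemplateSet(sequences=[], counts=np.asarray([], dtype=int),
                           frequencies=np.asarray([], dtype=float))
    counts = np.asarray(sizes, dtype=int)
    if all(f is not None for f in freqs):
        frequencies = np.asarray(freqs, dtype=float)
        frequencies = frequencies / frequencies.sum()
    else:
        frequencies = counts / counts.sum()
    return TemplateSet(sequences=seqs, counts=counts, frequencies=frequencies)


def population_from_fasta(path: str | PathLike) -> WeightedPopulation:
    """Load an annotated FASTA as a normalized WeightedPopulation."""
    templates = read_templates(path)
    return templates.as_population()
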