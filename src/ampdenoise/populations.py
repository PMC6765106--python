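"""Weighted sequence populations: inferred template sets and ground truths."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_FREQ_TOL = 1e-6


@dataclass
class WeightedPopulation:
    """A set of sequences with normalized frequencies.

    Frequencies must be non-negative and sum to 1 within 1e-6; callers
    convert counts to frequencies explicitly (no silent renormalization).
    """

    sequences: list[str]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.sequences) != self.frequencies.size:
            raise ValueError("sequences and frequencies differ in length")
        if self.frequencies.size == 0:
            raise ValueError("population is empty")
        if (self.frequencies < 0).any():
            raise ValueError("frequencies must be non-negative")
        total = float(self.frequencies.sum())
        if abs(total - 1.0) > _FREQ_TOL:
            raise ValueError(
                f"frequencies must sum to 1 (got {total!r}); "
                "normalize counts before constructing a population"
            )

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class TemplateSet:
    """Inferred (or true) template sequences with read counts and frequencies."""

    sequences: list[str]
    counts: np.ndarray
    frequencies: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.sequences) != self.counts.size:
            raise ValueError("sequences and counts differ in length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("template sequences must be unique")
        if self.frequencies is None:
            total = self.counts.sum()
            self.frequencies = (
                self.counts / total if total > 0 else np.asarray([], dtype=float)
            )
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size and abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def __len__(self) -> int:
        return len(self.sequences)

    def as_population(self) -> WeightedPopulation:
        return WeightedPopulation(
            sequences=list(self.sequences), frequencies=self.frequencies.copy()
        )
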