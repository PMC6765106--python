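"""Synthetic template populations and CCS-like reads with realistic errors.

The generator emulates the dominant long-read CCS error structure:
independent per-base substitutions plus indel errors concentrated in
homopolymer regions, with the per-run indel probability increasing
linearly with run length (one candidate ±1-unit length change per run).
Under this model the expected indel count per read is close to
``indel_base_rate * read_length`` (every base belongs to exactly one run),
so the total per-base error rate is ``sub_rate + indel_base_rate`` to a
good approximation.

Quality strings are constant-Phred per read, chosen so the quality-derived
expected error count matches the profile's realized per-base error rate on
that template; the denoising algorithms consume only aggregate expected
errors, so per-base quality variation is deliberately not modelled.

All outputs are pure functions of their parameters and ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .populations import WeightedPopulation
from .seq_io import Read
from .smd import edit_distance

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DEFAULT_SEED_SEQUENCE_RNG = 20190816
_DEFAULT_AMPLICON_LENGTH = 2600
_MAX_PHRED = 93


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base substitution and per-homopolymer-unit indel rates.

    ``sub_rate`` and ``indel_base_rate`` are the *nominal* (worst-read)
    rates. ``rate_spread`` models the read-to-read accuracy variation of
    circular consensus sequencing, where the number of passes — and hence
    the error rate — varies substantially between molecules: each read
    draws a rate multiplier uniformly from ``[1 - rate_spread, 1]``. With
    the default of 0 every read carries exactly the nominal rates, which
    emulates a population sitting at a filtering cutoff; a positive spread
    emulates a dataset *filtered at* the nominal rate, where most retained
    reads are better than the threshold.

    ``quality`` optionally pins the constant Phred value of simulated
    reads; when ``None`` it is derived per read from that read's realized
    error rate, so quality-predicted and realized expected errors agree in
    distribution.
    """

    sub_rate: float
    indel_base_rate: float
    quality: int | None = None
    rate_spread: float = 0.0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.indel_base_rate):
            if not (0.0 <= rate <= 0.2):
                raise ValueError("error rates must be in [0, 0.2]")
        if not (0.0 <= self.rate_spread < 1.0):
            raise ValueError("rate_spread must be in [0, 1)")


#: Short-and-accurate regime: total ~3.75e-4 errors/base (~0.97 expected
#: errors on a 2.6 kb read, ~38% of reads error free), with the error mass
#: split ~20% substitutions / ~80% homopolymer indels.
LOW_ERROR_PROFILE = ErrorProfile(sub_rate=7.5e-5, indel_base_rate=3.0e-4)

#: Long-and-inaccurate regime: a population filtered at ~1e-2 errors/base,
#: indel-heavy (80% homopolymer indels), leaving essentially no error-free
#: reads on multi-kilobase amplicons. Per-read rates spread below the
#: 1% cutoff the way pass-number variation spreads CCS accuracies.
HIGH_ERROR_PROFILE = ErrorProfile(
    sub_rate=2.0e-3, indel_base_rate=8.0e-3, rate_spread=0.75
)


@dataclass
class GroundTruth:
    """Bookkeeping linking simulated reads back to their templates."""

    templates: WeightedPopulation
    read_origins: np.ndarray
    errors_per_read: np.ndarray


def default_seed_sequence(length: int = _DEFAULT_AMPLICON_LENGTH) -> str:
    """Deterministic pseudo-random DNA at the scale of a ~2.6 kb amplicon."""
    rng = np.random.default_rng(_DEFAULT_SEED_SEQUENCE_RNG)
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def homopolymer_runs(sequence: str) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of identical bases (length >= 1)."""
    runs = []
    start = 0
    for i in range(1, len(sequence) + 1):
        if i == len(sequence) or sequence[i] != sequence[start]:
            runs.append((start, i - start))
            start = i
    return runs


def _expected_errors_per_read(template: str, profile: ErrorProfile) -> float:
    runs = homopolymer_runs(template)
    e_indel = sum(min(1.0, profile.indel_base_rate * r) for _, r in runs)
    return len(template) * profile.sub_rate + e_indel


def _quality_for(template: str, profile: ErrorProfile) -> int:
    if profile.quality is not None:
        return profile.quality
    p_eff = _expected_errors_per_read(template, profile) / len(template)
    if p_eff <= 0:
        return _MAX_PHRED
    return max(2, min(_MAX_PHRED, round(-10.0 * math.log10(p_eff))))


def _mutate_template(
    sequence: str, n_subs: int, n_indels: int, rng: np.random.Generator
) -> str:
    """Apply a fixed number of random substitutions and indels."""
    chars = list(sequence)
    if n_subs:
        for pos in rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False):
            old = chars[pos]
            choices = [b for b in "ACGT" if b != old]
            chars[pos] = choices[rng.integers(0, 3)]
    for _ in range(n_indels):
        pos = int(rng.integers(0, len(chars)))
        if rng.integers(0, 2) == 0 and len(chars) > 1:
            del chars[pos]
        else:
            chars.insert(pos, "ACGT"[rng.integers(0, 4)])
    return "".join(chars)


def generate_templates(
    seed_sequence: str,
    n_templates: int,
    subs_per_template: int,
    indels_per_template: int,
    min_pairwise_distance: int,
    rng_seed: int,
) -> WeightedPopulation:
    """Closely related template variants of a seed sequence.

    Each template carries the stated number of random substitutions and
    indels; proposals are rejection-resampled until every pairwise edit
    distance reaches ``min_pairwise_distance``. Frequencies are drawn
    uniform and normalized. Fully reproducible from ``rng_seed``.
    """
    if len(seed_sequence) < 500:
        raise ValueError("seed sequence must be at least 500 bp")
    rng = np.random.default_rng(rng_seed)
    templates: list[str] = []
    for _ in range(n_templates):
        for attempt in range(1000):
            candidate = _mutate_template(
                seed_sequence, subs_per_template, indels_per_template, rng
            )
            if all(
                edit_distance(candidate, prev) >= max(min_pairwise_distance, 1)
                for prev in templates
            ):
                templates.append(candidate)
                break
        else:
            raise RuntimeError(
                "could not satisfy the pairwise distance constraint after "
                "1000 resamples; lower min_pairwise_distance or add mutations"
            )
    freqs = rng.uniform(size=n_templates)
    return WeightedPopulation(sequences=templates, frequencies=freqs / freqs.sum())


class _TemplateModel:
    """Precomputed per-template state for fast read simulation."""

    def __init__(self, template: str, profile: ErrorProfile):
        self.template = template
        self.codes = np.frombuffer(template.encode("ascii"), dtype=np.uint8)
        self.code4 = np.searchsorted(_BASES, self.codes)  # ACGT -> 0..3
        runs = homopolymer_runs(template)
        self.run_starts = np.asarray([s for s, _ in runs], dtype=int)
        self.run_lengths = np.asarray([r for _, r in runs], dtype=int)
        self.run_rates = profile.indel_base_rate * self.run_lengths
        self.nominal_rate = _expected_errors_per_read(template, profile) / len(
            template
        )
        self.quality = _quality_for(template, profile)
        self.profile = profile

    def _read_quality(self, multiplier: float) -> int:
        if self.profile.quality is not None:
            return self.profile.quality
        p = multiplier * self.nominal_rate
        if p <= 0:
            return _MAX_PHRED
        return max(2, min(_MAX_PHRED, round(-10.0 * math.log10(p))))

    def sample(self, rng: np.random.Generator) -> tuple[str, int, int]:
        """One noisy read: (sequence, error-event count, Phred quality)."""
        profile = self.profile
        length = self.codes.size
        code4 = self.code4
        n_events = 0
        if profile.rate_spread > 0:
            multiplier = float(rng.uniform(1.0 - profile.rate_spread, 1.0))
        else:
            multiplier = 1.0
        if profile.sub_rate > 0:
            sub_pos = np.flatnonzero(
                rng.random(length) < multiplier * profile.sub_rate
            )
            if sub_pos.size:
                code4 = code4.copy()
                shift = rng.integers(1, 4, size=sub_pos.size)
                code4[sub_pos] = (code4[sub_pos] + shift) % 4
                n_events += int(sub_pos.size)
        seq = bytes(_BASES[code4]).decode("ascii")
        if profile.indel_base_rate > 0:
            probs = np.minimum(1.0, multiplier * self.run_rates)
            hits = np.flatnonzero(rng.random(self.run_rates.size) < probs)
            if hits.size:
                insert = rng.integers(0, 2, size=hits.size).astype(bool)
                parts: list[str] = []
                prev = 0
                for h, ins in zip(hits, insert):
                    start = int(self.run_starts[h])
                    base = self.template[start]
                    if ins:
                        parts.append(seq[prev:start])
                        parts.append(base)
                        prev = start
                    else:
                        parts.append(seq[prev:start])
                        prev = start + 1
                parts.append(seq[prev:])
                seq = "".join(parts)
                n_events += int(hits.size)
        return seq, n_events, self._read_quality(multiplier)


def simulate_reads(
    truth: WeightedPopulation,
    n_reads: int,
    profile: ErrorProfile,
    rng_seed: int,
    origins: np.ndarray | None = None,
) -> tuple[list[Read], GroundTruth]:
    """Draw noisy reads from a weighted template population.

    Each read samples a template by frequency (or follows an explicit
    ``origins`` array), then receives per-base substitutions and one
    candidate homopolymer length-change per run with probability
    ``min(1, indel_base_rate * run_length)``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if origins is None:
        origins = rng.choice(len(truth), size=n_reads, p=truth.frequencies)
    origins = np.asarray(origins, dtype=int)
    models = [_TemplateModel(t, profile) for t in truth.sequences]
    reads: list[Read] = []
    errors = np.zeros(origins.size, dtype=int)
    for i, origin in enumerate(origins):
        seq, n_events, phred = models[origin].sample(rng)
        errors[i] = n_events
        quality = np.full(len(seq), phred, dtype=np.int16)
        reads.append(Read(id=f"read{i}", sequence=seq, quality=quality))
    return reads, GroundTruth(
        templates=truth, read_origins=origins, errors_per_read=errors
    )


def _child_seeds(rng_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(rng_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def mvc_fixture(kind: str, rng_seed: int) -> tuple[list[Read], GroundTruth]:
    """Canned mock-community parameterizations for end-to-end testing.

    ``low_error``: 20 templates at 2.6 kb scale (pairwise >= 3 edits),
    100 reads each under the low-error profile. ``high_error``: 10
    templates, 200 reads each under the indel-heavy 1% profile.
    ``single_base_pair``: two templates differing by exactly one
    substitution, 500 reads each under the low-error profile.
    """
    seed_t, seed_r, seed_p = _child_seeds(rng_seed, 3)
    seed_seq = default_seed_sequence()
    if kind == "low_error":
        pop = generate_templates(seed_seq, 20, 10, 3, 3, seed_t)
        per_template = 100
        profile = LOW_ERROR_PROFILE
    elif kind == "high_error":
        pop = generate_templates(seed_seq, 10, 10, 3, 3, seed_t)
        per_template = 200
        profile = HIGH_ERROR_PROFILE
    elif kind == "single_base_pair":
        rng = np.random.default_rng(seed_p)
        pos = int(rng.integers(100, len(seed_seq) - 100))
        old = seed_seq[pos]
        new = [b for b in "ACGT" if b != old][rng.integers(0, 3)]
        variant = seed_seq[:pos] + new + seed_seq[pos + 1 :]
        pop = WeightedPopulation(
            sequences=[seed_seq, variant], frequencies=np.asarray([0.5, 0.5])
        )
        per_template = 500
        profile = LOW_ERROR_PROFILE
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    n = len(pop)
    # Exact per-template coverage: truth frequencies equal the empirical
    # origin frequencies, so metric scores reflect reconstruction error
    # rather than multinomial sampling noise.
    truth = WeightedPopulation(
        sequences=list(pop.sequences), frequencies=np.full(n, 1.0 / n)
    )
    origins = np.repeat(np.arange(n), per_template)
    reads, ground_truth = simulate_reads(
        truth, origins.size, profile, seed_r, origins=origins
    )
    return reads, ground_truth
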