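"""Seeded synthetic data: random circular sequences with planted R/Y
patterns, reverse-complement-symmetric tetramer tables, and PWMs with a
known consensus.

Everything here is deterministic in its seed, so tests and command-line
simulations are exactly reproducible.  The generators emulate the study
conditions the analysis modules target: a ~600 bp circular substrate with
balanced base composition, a density-derived query profile carrying a small
number of miscalled and unresolved bases, a complete positive-valued
tetramer deformability table, and a motif matrix whose best-scoring window
is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .deformability import TetramerTable
from .motif import PWM
from .register import RYProfile
from .sequences import CircularSequence, reverse_complement

_PURINES = "AG"
_PYRIMIDINES = "CT"


@dataclass(frozen=True)
class Plant:
    """A pattern planted into a synthetic sequence.

    ``profile`` is the clean R/Y string written (as nucleotides) at
    1-based ``position``; ``n_mismatch``/``n_unresolved`` control how many
    positions of the *query* profile (see :func:`planted_query`) are
    flipped or blanked to X relative to the planted truth, emulating
    density miscalls and unresolvable bases.
    """

    profile: str
    position: int
    n_mismatch: int = 0
    n_unresolved: int = 0

    def __post_init__(self) -> None:
        RYProfile(self.profile)  # validate alphabet
        determined = sum(1 for c in self.profile if c != "X")
        if self.n_mismatch + self.n_unresolved > determined:
            raise ValueError("more planted defects than determined profile positions")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    length: int
    gc_fraction: float = 0.5
    plant: Plant | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.plant is not None and len(self.plant.profile) > self.length:
            raise ValueError("planted profile longer than the sequence")


def synth_sequence(spec: SyntheticSpec) -> CircularSequence:
    """Seeded random circular sequence, optionally with a planted pattern.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) =
    (1-gc)/2.  When a plant is present, a nucleotide realisation of its
    R/Y profile (purines for R, pyrimidines for Y, free draw for X)
    overwrites the background at the planted position, wrapping if needed.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = list(rng.choice(list("ACGT"), size=spec.length, p=probs))
    if spec.plant is not None:
        sub = np.random.default_rng([spec.seed, 101])
        L = spec.length
        for offset, symbol in enumerate(spec.plant.profile):
            idx = (spec.plant.position - 1 + offset) % L
            if symbol == "R":
                bases[idx] = _PURINES[sub.integers(2)]
            elif symbol == "Y":
                bases[idx] = _PYRIMIDINES[sub.integers(2)]
            else:  # X: any base
                bases[idx] = "ACGT"[sub.integers(4)]
    return CircularSequence("".join(bases), circular=True, origin_label=f"seed={spec.seed}")


def planted_query(spec: SyntheticSpec) -> RYProfile:
    """The density-like query profile for a planted spec.

    Starts from the planted truth and, at seeded disjoint positions among
    the determined symbols, flips ``n_mismatch`` symbols (R <-> Y) and
    blanks ``n_unresolved`` to X.  Scanning the synthesised sequence with
    this query therefore yields exactly those defect counts at the plant.
    """
    if spec.plant is None:
        raise ValueError("spec has no plant")
    plant = spec.plant
    rng = np.random.default_rng([spec.seed, 202])
    symbols = list(plant.profile)
    determined = [i for i, c in enumerate(symbols) if c != "X"]
    chosen = rng.choice(
        len(determined), size=plant.n_mismatch + plant.n_unresolved, replace=False
    )
    flip = {"R": "Y", "Y": "R"}
    for j in chosen[: plant.n_mismatch]:
        i = determined[j]
        symbols[i] = flip[symbols[i]]
    for j in chosen[plant.n_mismatch :]:
        symbols[determined[j]] = "X"
    return RYProfile("".join(symbols), source="density")


def synth_table(seed: int, low: float = 1.0, high: float = 8.0) -> TetramerTable:
    """Complete reverse-complement-symmetric tetramer table with values
    drawn uniformly from [low, high], one draw per strand-symmetric class."""
    if not 0 < low <= high:
        raise ValueError("require 0 < low <= high")
    rng = np.random.default_rng(seed)
    entries: dict[str, float] = {}
    for tet in ("".join(t) for t in product("ACGT", repeat=4)):
        rc = reverse_complement(tet)
        rep = min(tet, rc)
        if rep not in entries:
            entries[rep] = float(rng.uniform(low, high))
        entries[tet] = entries[rep]
    table = TetramerTable(entries, metadata=f"synthetic seed={seed}")
    assert table.is_complete()
    return table


def synth_pwm(
    seed: int,
    width: int = 20,
    region_lengths: tuple[int, int, int] | None = None,
) -> tuple[PWM, str]:
    """Random PWM with a known consensus.

    Non-consensus weights are negative draws; the consensus base of each
    column gets a strictly larger positive weight, so the consensus string
    is the unique global-maximum window by construction.  Returns
    ``(pwm, consensus)``.
    """
    rng = np.random.default_rng(seed)
    weights = rng.uniform(-2.0, -0.2, size=(4, width))
    consensus_idx = rng.integers(0, 4, size=width)
    for j, i in enumerate(consensus_idx):
        weights[i, j] = rng.uniform(0.3, 1.5)
    pwm = PWM(weights, region_lengths)
    consensus = "".join("ACGT"[i] for i in consensus_idx)
    return pwm, consensus
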