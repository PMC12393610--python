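"""Purine/pyrimidine register mapping on circular DNA.

CryoEM density at ~3 Å resolves whether a base is a purine (R: large,
two-ring) or a pyrimidine (Y: single-ring) long before it resolves its
identity.  A strand of n consecutive R/Y calls is therefore a shape-derived
barcode that can be matched against the known sequence of the substrate to
establish the nucleotide register of a model.  This module implements that
matching: R/Y conversion, circular both-strand scanning with a tolerance
budget for miscalled (mismatch) and uncallable (X, unresolved) bases, the
analytic probability that a random R/Y string would match by chance, and the
substitution of real sequence back into a matched window.  It also finds
reverse-complement palindromes, which mark symmetric protein binding sites.

Coordinates are 1-based inclusive throughout; on circular references
position L is followed by position 1 and intervals with start > end wrap
through the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator

from .sequences import CircularSequence, reverse_complement

RY_ALPHABET = frozenset("RYX")

_TO_RY = str.maketrans("AGCT", "RRYY")
_RY_COMPLEMENT = str.maketrans("RY", "YR")


@dataclass(frozen=True)
class RYProfile:
    """A purine/pyrimidine annotation string.

    ``symbols`` is a string over {R, Y, X}; X marks a base whose density
    could not be classified and is only legal for density-derived profiles
    (``source="density"``).  Sequence-derived profiles are always fully
    determined.
    """

    symbols: str
    source: str = "density"

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("profile must be non-empty")
        if self.source not in ("density", "sequence"):
            raise ValueError(f"unknown profile source {self.source!r}")
        for i, ch in enumerate(self.symbols):
            if ch not in RY_ALPHABET:
                raise ValueError(f"invalid profile symbol {ch!r} at position {i + 1}")
        if self.source == "sequence" and "X" in self.symbols:
            raise ValueError("sequence-derived profiles cannot contain X")

    def __len__(self) -> int:
        return len(self.symbols)


def to_ry(seq) -> RYProfile:
    """Convert a nucleotide sequence to its R/Y profile (A,G -> R; C,T -> Y)."""
    residues = seq.residues if isinstance(seq, CircularSequence) else str(seq).upper()
    for i, ch in enumerate(residues):
        if ch not in "ACGT":
            raise ValueError(
                f"non-canonical nucleotide {ch!r} at position {i + 1}; expected A/C/G/T"
            )
    return RYProfile(residues.translate(_TO_RY), source="sequence")


def complement_ry(profile: RYProfile) -> RYProfile:
    """Base-pairing complement of an R/Y profile: R <-> Y, X fixed.

    Each Watson-Crick pair holds one purine and one pyrimidine, so the
    profile of the paired strand (read in the same direction) swaps R and Y.
    An involution.
    """
    return RYProfile(profile.symbols.translate(_RY_COMPLEMENT), source=profile.source)


def match_probability(n: int, f: int) -> float:
    """Probability that a random R/Y string of length n matches a fixed
    profile with at most ``f`` free positions (mismatched or unresolved).

    Each of the n positions of a random sequence is R or Y with probability
    1/2, so P = 2^-n * sum_{i=0..f} C(n, i).
    """
    if n < 1:
        raise ValueError(f"profile length must be >= 1, got {n}")
    if not 0 <= f <= n:
        raise ValueError(f"free positions f={f} must satisfy 0 <= f <= n={n}")
    hits = sum(math.comb(n, i) for i in range(f + 1))
    return hits / 2**n


def one_in_n(n: int, f: int) -> int:
    """The '1 in N' odds denominator: reciprocal of :func:`match_probability`
    rounded to the nearest integer (exact integer arithmetic)."""
    hits = sum(math.comb(n, i) for i in range(f + 1))
    return round(Fraction(2**n, hits))


def count_agreements(assigned: RYProfile, reference: RYProfile) -> tuple[int, int, int]:
    """Positionwise comparison of a density-derived profile with the
    sequence-derived truth.

    Returns ``(n_agree, n_mismatch, n_unresolved)``; an X in ``assigned``
    counts as unresolved, an unequal pair of determined symbols as a
    mismatch.  The reference must be fully determined.
    """
    if len(assigned) != len(reference):
        raise ValueError(
            f"profile lengths differ: {len(assigned)} vs {len(reference)}"
        )
    if "X" in reference.symbols:
        raise ValueError("reference profile must not contain X")
    agree = mismatch = unresolved = 0
    for a, r in zip(assigned.symbols, reference.symbols):
        if a == "X":
            unresolved += 1
        elif a == r:
            agree += 1
        else:
            mismatch += 1
    return agree, mismatch, unresolved


@dataclass(frozen=True)
class MatchHit:
    """One alignment of a density profile to the reference.

    ``start`` is the 1-based forward-strand position of the 5'-most aligned
    reference base.  For ``strand="reverse"`` the profile was reversed and
    R/Y-complemented before comparison, so the hit still occupies forward
    positions ``start .. start + n - 1`` (modulo L).  ``free`` is the spent
    tolerance budget, n_mismatch + n_unresolved.
    """

    start: int
    strand: str
    n: int
    n_agree: int
    n_mismatch: int
    n_unresolved: int
    probability: float

    def __post_init__(self) -> None:
        if self.n_agree + self.n_mismatch + self.n_unresolved != self.n:
            raise ValueError("agreement counts must sum to the profile length")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def free(self) -> int:
        return self.n_mismatch + self.n_unresolved


@dataclass
class ScanResult:
    """Hits from :func:`scan`, sorted by (free positions, start, strand).

    ``unique`` is true when exactly one hit attains the minimum number of
    free positions — the condition under which a register assignment is
    trustworthy.  Behaves as a sequence of :class:`MatchHit`.
    """

    hits: list[MatchHit] = field(default_factory=list)

    def __iter__(self) -> Iterator[MatchHit]:
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def __getitem__(self, i):
        return self.hits[i]

    @property
    def best(self) -> MatchHit | None:
        return self.hits[0] if self.hits else None

    @property
    def unique(self) -> bool:
        if not self.hits:
            return False
        m = self.hits[0].free
        return sum(1 for h in self.hits if h.free == m) == 1


def _compare(window_ry: str, profile: str) -> tuple[int, int, int]:
    agree = mismatch = unresolved = 0
    for p, w in zip(profile, window_ry):
        if p == "X":
            unresolved += 1
        elif p == w:
            agree += 1
        else:
            mismatch += 1
    return agree, mismatch, unresolved


def scan(profile: RYProfile, ref: CircularSequence, max_free: int) -> ScanResult:
    """Scan both strands of a reference for a density-derived R/Y profile.

    Every start position (all L of them on a circle, L - n + 1 on a linear
    reference) on both strands whose mismatch + unresolved count is within
    ``max_free`` is reported.  The reverse strand is searched by comparing
    the reversed, R/Y-complemented profile against the forward reference, so
    all coordinates stay on the forward strand.
    """
    if max_free < 0:
        raise ValueError("max_free must be >= 0")
    n = len(profile)
    L = len(ref)
    if n > L:
        raise ValueError(f"profile length {n} exceeds reference length {L}")
    ref_ry = to_ry(ref).symbols
    if ref.circular:
        starts = range(1, L + 1)
        doubled = ref_ry + ref_ry
    else:
        starts = range(1, L - n + 2)
        doubled = ref_ry
    queries = {
        "forward": profile.symbols,
        "reverse": complement_ry(RYProfile(profile.symbols[::-1])).symbols,
    }
    hits: list[MatchHit] = []
    for strand, query in queries.items():
        for s in starts:
            window = doubled[s - 1 : s - 1 + n]
            agree, mm, unres = _compare(window, query)
            if mm + unres <= max_free:
                hits.append(
                    MatchHit(
                        start=s,
                        strand=strand,
                        n=n,
                        n_agree=agree,
                        n_mismatch=mm,
                        n_unresolved=unres,
                        probability=match_probability(n, mm + unres),
                    )
                )
    hits.sort(key=lambda h: (h.free, h.start, h.strand))
    return ScanResult(hits)


@dataclass(frozen=True)
class RegisterAssignment:
    """A matched window widened into a nucleotide register assignment.

    ``mapped_range`` is the inclusive 1-based forward-strand interval
    (start > end denotes wrap through the origin); ``chain_sequence`` is the
    reference sequence over that interval, reverse-complemented for hits on
    the reverse strand so that it reads 5'->3' along the modelled chain.
    """

    hit: MatchHit
    mapped_range: tuple[int, int]
    chain_sequence: str


def assign_register(
    hit: MatchHit,
    ref: CircularSequence,
    extend_left: int = 0,
    extend_right: int = 0,
) -> RegisterAssignment:
    """Substitute reference sequence back into a matched (optionally widened)
    window.

    ``extend_left``/``extend_right`` widen the matched interval in forward
    reference coordinates.  On a linear reference an extension past either
    end is an error; on a circle it wraps.
    """
    if extend_left < 0 or extend_right < 0:
        raise ValueError("extensions must be >= 0")
    L = len(ref)
    length = hit.n + extend_left + extend_right
    if length > L:
        raise ValueError("extended interval longer than the reference")
    start = hit.start - extend_left
    if ref.circular:
        start = (start - 1) % L + 1
    elif start < 1 or start + length - 1 > L:
        raise ValueError("extension beyond the end of a linear reference")
    end = start + length - 1
    if ref.circular:
        end = (end - 1) % L + 1
    fragment = ref.fragment(start, length)
    if hit.strand == "reverse":
        fragment = reverse_complement(fragment)
    return RegisterAssignment(hit=hit, mapped_range=(start, end), chain_sequence=fragment)


@dataclass(frozen=True)
class PalindromeHit:
    """A maximal reverse-complement palindrome (inclusive 1-based interval;
    start > end denotes circular wrap)."""

    start: int
    end: int
    length: int


def find_palindromes(seq: CircularSequence, min_len: int = 4) -> list[PalindromeHit]:
    """All maximal even-length substrings equal to their own reverse
    complement, of length >= ``min_len``.

    Maximal means not extensible by one base on both sides; every
    palindromic center yields at most one hit.  On circular sequences
    centers may sit across the origin and arms may wrap, capped at L // 2
    per arm so a hit never overlaps itself.
    """
    if min_len < 2 or min_len % 2:
        raise ValueError("min_len must be an even integer >= 2")
    s = seq.residues
    L = len(s)
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def base(i: int) -> str | None:  # 0-based, wrap on circles
        if seq.circular:
            return s[i % L]
        if 0 <= i < L:
            return s[i]
        return None

    max_arm = L // 2
    centers = range(L) if seq.circular else range(L - 1)
    hits: list[PalindromeHit] = []
    for c in centers:  # center between 0-based positions c and c+1
        arm = 0
        while arm < max_arm:
            left = base(c - arm)
            right = base(c + 1 + arm)
            if left is None or right is None or pair[left] != right:
                break
            arm += 1
        if 2 * arm >= min_len:
            start0 = c - arm + 1
            end0 = c + arm
            if seq.circular:
                start = start0 % L + 1
                end = end0 % L + 1
            else:
                start = start0 + 1
                end = end0 + 1
            hits.append(PalindromeHit(start=start, end=end, length=2 * arm))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def interval_positions(
    interval: tuple[int, int], L: int, circular: bool
) -> list[int]:
    """The 1-based positions covered by an inclusive interval (wrap-aware)."""
    start, end = interval
    if not (1 <= start <= L and 1 <= end <= L):
        raise ValueError(f"interval {interval} outside reference of length {L}")
    if start <= end:
        return list(range(start, end + 1))
    if not circular:
        raise ValueError(f"interval {interval} wraps but reference is linear")
    return list(range(start, L + 1)) + list(range(1, end + 1))


def interval_overlap(
    a: tuple[int, int], b: tuple[int, int], L: int, circular: bool = True
) -> int:
    """Number of positions shared by two inclusive 1-based intervals."""
    pa = set(interval_positions(a, L, circular))
    pb = set(interval_positions(b, L, circular))
    return len(pa & pb)
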