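"""Circular DNA sequences with 1-based coordinates.

A :class:`CircularSequence` is the shared substrate for every analysis in this
package: register scanning, deformability profiling and motif scoring all
operate on a nucleotide string that may be covalently closed (a minicircle).
Positions are 1-based and inclusive, matching the numbering conventions used
for minicircle substrates in the structural literature; on a circular sequence
position ``L`` is followed by position ``1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

CANONICAL = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(seq: str) -> str:
    """Watson-Crick complement of a nucleotide string (same orientation)."""
    _validate_nucleotides(seq)
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return complement(seq)[::-1]


def _validate_nucleotides(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in CANONICAL:
            raise ValueError(
                f"non-canonical nucleotide {ch!r} at position {i + 1}; "
                "expected only A/C/G/T"
            )


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide sequence with optional circular topology.

    Parameters
    ----------
    residues
        Upper-case nucleotide string over A/C/G/T.
    circular
        Whether the molecule is covalently closed; position arithmetic is
        modulo length when true.
    origin_label
        Free-text note naming the numbering convention (e.g. which published
        sequence defines position 1).
    """

    residues: str
    circular: bool = True
    origin_label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        _validate_nucleotides(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, position: int) -> str:
        """Base at a 1-based position, wrapping modulo L when circular."""
        L = len(self.residues)
        if self.circular:
            return self.residues[(position - 1) % L]
        if not 1 <= position <= L:
            raise IndexError(f"position {position} outside linear sequence of length {L}")
        return self.residues[position - 1]

    def fragment(self, start: int, length: int) -> str:
        """Substring of ``length`` bases beginning at 1-based ``start``.

        Wraps around the origin for circular sequences; raises for linear
        sequences when the window runs off either end.
        """
        if length < 0:
            raise ValueError("fragment length must be non-negative")
        L = len(self.residues)
        if self.circular:
            i0 = (start - 1) % L
            doubled = self.residues + self.residues
            if length > L:
                raise ValueError(f"fragment length {length} exceeds circle length {L}")
            return doubled[i0 : i0 + length]
        if start < 1 or start + length - 1 > L:
            raise IndexError(
                f"fragment [{start}, {start + length - 1}] outside linear sequence of length {L}"
            )
        return self.residues[start - 1 : start - 1 + length]

    def interval(self, start: int, end: int) -> str:
        """Inclusive 1-based interval; ``start > end`` wraps on a circle."""
        L = len(self.residues)
        if self.circular and start > end:
            length = L - start + 1 + end
        else:
            if start > end:
                raise ValueError(f"interval start {start} > end {end} on linear sequence")
            length = end - start + 1
        return self.fragment(start, length)

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(
            reverse_complement(self.residues), self.circular, self.origin_label
        )

    def rotated(self, offset: int) -> "CircularSequence":
        """Sequence re-originated so old position ``offset + 1`` becomes 1."""
        if not self.circular:
            raise ValueError("rotation requires a circular sequence")
        L = len(self.residues)
        k = offset % L
        return CircularSequence(
            self.residues[k:] + self.residues[:k], True, self.origin_label
        )


def read_fasta(path, circular: bool | None = None) -> CircularSequence:
    """Read the first record of a FASTA file as a :class:`CircularSequence`.

    Topology is taken from an explicit ``circular`` argument when given,
    otherwise from a ``circular=true`` keyword in the record description,
    defaulting to linear.
    """
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ValueError(f"no FASTA records in {path}")
    if circular is None:
        circular = "circular=true" in record.description.lower()
    return CircularSequence(str(record.seq).upper(), circular, origin_label=record.id)


def write_fasta(seq: CircularSequence, path, name: str = "sequence") -> None:
    """Write a sequence as single-record FASTA, encoding topology in the header."""
    topo = "circular=true" if seq.circular else "circular=false"
    with open(path, "w") as fh:
        fh.write(f">{name} {topo}\n")
        for i in range(0, len(seq.residues), 70):
            fh.write(seq.residues[i : i + 70] + "\n")
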