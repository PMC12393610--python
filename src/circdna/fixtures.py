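"""Built-in reference payloads.

Small data items that the rest of the package (and its test-suite) treats
as ground truth: the two density-derived R/Y assignment tables for the
gyrase G-segment structures (wrapped and not-wrapped complexes), the
G-segment overlap palindrome, and the step-parameter presets used for the
superhelix handedness demonstrations.  Each payload is integrity-checked
against an embedded SHA-256 at access time so an accidental edit fails
loudly rather than silently shifting downstream numbers.

The assignment tables keep their published residue numbering (chain E
positions 92–115 / 1–30) verbatim, so code using them reads like the
printed tables.  Row layout: (position_E, assignment_E, pattern_E,
pattern_F, assignment_F, position_F), where "assignment" is the call made
from density (R/Y/X) and "pattern" the truth derived from the known
minicircle sequence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Any

from .register import RYProfile

# wrapped-complex G-segment: 24 bp, one miscall (E position 102) and one
# unresolvable base (E position 110)
_TABLE1_ROWS = [
    (92, "R", "R", "Y", "Y", 27),
    (93, "Y", "Y", "R", "R", 26),
    (94, "Y", "Y", "R", "R", 25),
    (95, "R", "R", "Y", "Y", 24),
    (96, "Y", "Y", "R", "R", 23),
    (97, "R", "R", "Y", "Y", 22),
    (98, "R", "R", "Y", "Y", 21),
    (99, "R", "R", "Y", "Y", 20),
    (100, "R", "R", "Y", "Y", 19),
    (101, "Y", "Y", "R", "R", 18),
    (102, "Y", "R", "Y", "R", 17),
    (103, "R", "R", "Y", "Y", 16),
    (104, "Y", "Y", "R", "R", 15),
    (105, "R", "R", "Y", "Y", 14),
    (106, "R", "R", "Y", "Y", 13),
    (107, "Y", "Y", "R", "R", 12),
    (108, "Y", "Y", "R", "R", 11),
    (109, "R", "R", "Y", "Y", 10),
    (110, "X", "R", "Y", "X", 9),
    (111, "Y", "Y", "R", "R", 8),
    (112, "R", "R", "Y", "Y", 7),
    (113, "R", "R", "Y", "Y", 6),
    (114, "R", "R", "Y", "Y", 5),
    (115, "Y", "Y", "R", "R", 4),
]

# not-wrapped-complex G-segment: 30 bp, two miscalls (E positions 26, 30)
_TABLE2_ROWS = [
    (1, "R", "R", "Y", "Y", 30),
    (2, "R", "R", "Y", "Y", 29),
    (3, "R", "R", "Y", "Y", 28),
    (4, "Y", "Y", "R", "R", 27),
    (5, "Y", "Y", "R", "R", 26),
    (6, "Y", "Y", "R", "R", 25),
    (7, "R", "R", "Y", "Y", 24),
    (8, "R", "R", "Y", "Y", 23),
    (9, "R", "R", "Y", "Y", 22),
    (10, "Y", "Y", "R", "R", 21),
    (11, "Y", "Y", "R", "R", 20),
    (12, "Y", "Y", "R", "R", 19),
    (13, "R", "R", "Y", "Y", 18),
    (14, "R", "R", "Y", "Y", 17),
    (15, "Y", "Y", "R", "R", 16),
    (16, "R", "R", "Y", "Y", 15),
    (17, "Y", "Y", "R", "R", 14),
    (18, "Y", "Y", "R", "R", 13),
    (19, "R", "R", "Y", "Y", 12),
    (20, "R", "R", "Y", "Y", 11),
    (21, "R", "R", "Y", "Y", 10),
    (22, "R", "R", "Y", "Y", 9),
    (23, "R", "R", "Y", "Y", 8),
    (24, "R", "R", "Y", "Y", 7),
    (25, "R", "R", "Y", "Y", 6),
    (26, "R", "Y", "R", "Y", 5),
    (27, "R", "R", "Y", "Y", 4),
    (28, "R", "R", "Y", "Y", 3),
    (29, "Y", "Y", "R", "R", 2),
    (30, "R", "Y", "R", "Y", 1),
]

_PALINDROME = "GAATTC"

# Shift, Slide, Rise (A); Tilt, Roll, Twist (deg) for the three helix forms
# used in the superhelix handedness demonstration
_FIGS4_PRESETS = {
    "B": (0.0, 0.0, 3.4, 0.0, 0.0, 36.0),
    "A": (0.0, -2.0, 3.4, 0.0, 12.0, 34.0),
    "C": (0.0, 2.0, 3.4, 0.0, -12.0, 38.298),
}


def _digest(payload: Any) -> str:
    return hashlib.sha256(repr(payload).encode()).hexdigest()


_CHECKSUMS = {
    "table1": "14869b7b51a88b5a9ad30e90df231a1ebd735398add3178e626a4747db24ae1d",
    "table2": "bbaafe01cd5084e9e185a5562aad53e82258b085ba19f7286b42d6f924043ba2",
    "palindrome": "3a04dd7d16fa3c90798b715e0d43a59a99bcdca52ba1f2a5203cd66f26447abc",
    "figS4_presets": "6dd33435a30f275a37dc5d637029b86223f82a9ebec7b07637bf26f057698f2d",
}

_PAYLOADS: dict[str, Any] = {
    "table1": _TABLE1_ROWS,
    "table2": _TABLE2_ROWS,
    "palindrome": _PALINDROME,
    "figS4_presets": _FIGS4_PRESETS,
}

_CITATIONS = {
    "table1": "wrapped-complex G-segment density R/Y assignment (24 bp)",
    "table2": "not-wrapped-complex G-segment density R/Y assignment (30 bp)",
    "palindrome": "G-segment overlap palindrome",
    "figS4_presets": "superhelix demonstration step-parameter presets (B/A/C)",
}


@dataclass(frozen=True)
class Fixture:
    name: str
    payload: Any
    citation: str

    def chain_e_assignment(self) -> RYProfile:
        """Chain-E density assignment column as an R/Y profile."""
        return RYProfile("".join(r[1] for r in self.payload), source="density")

    def chain_e_pattern(self) -> RYProfile:
        """Chain-E sequence-truth pattern column as an R/Y profile."""
        return RYProfile("".join(r[2] for r in self.payload), source="sequence")

    def chain_f_assignment(self) -> RYProfile:
        return RYProfile("".join(r[4] for r in self.payload), source="density")

    def chain_f_pattern(self) -> RYProfile:
        return RYProfile("".join(r[3] for r in self.payload), source="sequence")


def fixture(name: str) -> Fixture:
    """Fetch a named payload, verifying its embedded checksum.

    Known names: ``table1``, ``table2``, ``palindrome``, ``figS4_presets``.
    """
    if name not in _PAYLOADS:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(sorted(_PAYLOADS))}"
        )
    payload = _PAYLOADS[name]
    digest = _digest(payload)
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name!r} failed its integrity check "
            f"(sha256 {digest}); the transcription has been altered"
        )
    return Fixture(name=name, payload=payload, citation=_CITATIONS[name])
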