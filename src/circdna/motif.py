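"""Position-weight-matrix scanning for the gyrase cleavage motif.

Genome-wide mapping of gyrase cleavage sites yields a 130 bp motif built of
three regions: a 47 bp stretch with periodic G/C content (wrapped around one
beta-pinwheel), a 36 bp core (the G-segment) and a second 47 bp periodic
stretch.  The motif is distributed as a 4 x W position weight matrix whose
additive score is calibrated so that positive values indicate a sequence
fitting the motif.  This module scores circular sequences against such a
PWM on both strands, splits the full matrix into the three documented
sub-matrices (first+core, core, core+second), and answers whether any
positive score lies within a window of a stated centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import CircularSequence, reverse_complement

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

DEFAULT_REGIONS = (47, 36, 47)


@dataclass
class PWM:
    """A 4 x W position weight matrix, rows ordered A, C, G, T.

    ``region_lengths`` declares the (first periodic, core, second periodic)
    partition of the columns; it must sum to W when declared.
    """

    weights: np.ndarray
    region_lengths: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("PWM must be a 4 x W matrix (rows A, C, G, T)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("PWM weights must be finite")
        if self.region_lengths is not None:
            if len(self.region_lengths) != 3 or any(r < 0 for r in self.region_lengths):
                raise ValueError("region_lengths must be three non-negative integers")
            if sum(self.region_lengths) != self.width:
                raise ValueError(
                    f"region lengths {self.region_lengths} do not sum to width {self.width}"
                )

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def center_column(self) -> int:
        """1-based centre column; even widths round toward the 5' end."""
        return (self.width + 1) // 2

    def consensus(self) -> str:
        """Highest-weight base per column (ties to the earlier base in ACGT)."""
        return "".join(BASE_ORDER[i] for i in np.argmax(self.weights, axis=0))

    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())


def read_pwm(path, region_lengths: tuple[int, int, int] | None = None) -> PWM:
    """Read a PWM from TSV: four labelled rows A/C/G/T, one column per
    motif position.

    ``region_lengths`` defaults to the 47/36/47 gyrase-motif partition when
    the width allows it, else undeclared.
    """
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    labels = [str(x).strip().upper() for x in df.index]
    if sorted(labels) != ["A", "C", "G", "T"]:
        raise ValueError(
            f"PWM must have exactly the four row labels A/C/G/T, got {labels}"
        )
    if df.isna().any().any():
        raise ValueError("PWM has ragged or non-numeric rows")
    mat = np.vstack([df.loc[b].to_numpy(dtype=float) for b in BASE_ORDER])
    if region_lengths is None and mat.shape[1] == sum(DEFAULT_REGIONS):
        region_lengths = DEFAULT_REGIONS
    return PWM(mat, region_lengths)


def write_pwm(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(BASE_ORDER):
            fh.write(b + "\t" + "\t".join(f"{v:.10g}" for v in pwm.weights[i]) + "\n")


@dataclass(frozen=True)
class MotifScore:
    """Additive PWM score of the window centred at a 1-based reference
    position on one strand."""

    position: int
    strand: str
    score: float


def _score_window(window: str, pwm: PWM) -> float:
    total = 0.0
    for j, base in enumerate(window):
        total += pwm.weights[_BASE_INDEX[base], j]
    return float(total)


def score_at(
    seq: CircularSequence, pwm: PWM, position: int, strand: str = "forward"
) -> MotifScore:
    """Score the motif window whose centre column sits at ``position``.

    The PWM centre column (even widths rounding toward 5') is aligned to
    the stated reference position; the reverse strand scores the reverse
    complement of the same forward-strand window.
    """
    if strand not in ("forward", "reverse"):
        raise ValueError(f"bad strand {strand!r}")
    W = pwm.width
    start = position - pwm.center_column + 1
    if not seq.circular:
        if start < 1 or start + W - 1 > len(seq):
            raise ValueError(
                f"motif window centred at {position} falls off the linear reference"
            )
    window = seq.fragment(start, W)
    if strand == "reverse":
        window = reverse_complement(window)
    return MotifScore(position=position, strand=strand, score=_score_window(window, pwm))


def scan_pwm(seq: CircularSequence, pwm: PWM) -> list[MotifScore]:
    """Score every centre position on both strands (all L centres on a
    circle; on linear references only fully contained windows)."""
    L = len(seq)
    W = pwm.width
    if seq.circular:
        positions = range(1, L + 1)
    else:
        positions = range(pwm.center_column, L - (W - pwm.center_column) + 1)
    out = []
    for strand in ("forward", "reverse"):
        for p in positions:
            out.append(score_at(seq, pwm, p, strand))
    return out


def split_pwm(pwm: PWM) -> tuple[PWM, PWM, PWM]:
    """Split a region-annotated PWM into (first+core, core, core+second).

    Columns are copied verbatim; each sub-matrix keeps a region annotation
    with the absent flank set to zero.
    """
    if pwm.region_lengths is None:
        raise ValueError("PWM has no declared region lengths; cannot split")
    r1, rc, r2 = pwm.region_lengths
    w = pwm.weights
    first_core = PWM(w[:, : r1 + rc].copy(), (r1, rc, 0))
    core = PWM(w[:, r1 : r1 + rc].copy(), (0, rc, 0))
    core_second = PWM(w[:, r1:].copy(), (0, rc, r2))
    return first_core, core, core_second


def positive_near_center(
    scores: list[MotifScore],
    center: int,
    L: int,
    radius: int = 5,
    circular: bool = True,
) -> tuple[bool, list[MotifScore]]:
    """Is any motif score positive within +/- ``radius`` bp of ``center``?

    Distance is circular when ``circular``; the window is inclusive at both
    ends.  Returns the verdict plus the supporting positive-score records.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    support = []
    for s in scores:
        d = abs(s.position - center)
        if circular:
            d = min(d, L - d)
        if d <= radius and s.score > 0:
            support.append(s)
    return bool(support), support


def scores_to_frame(scores: list[MotifScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [s.position for s in scores],
            "strand": [s.strand for s in scores],
            "score": [s.score for s in scores],
        }
    )
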