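"""Sequence-dependent DNA deformability profiling.

Each base-pair step has an intrinsic deformability (how cheaply the step can
bend, twist and shear away from its rest geometry) that depends on the step
and its immediate neighbours — a tetramer context.  Given a lookup table of
tetramer deformability values V_step (units deg^3 A^3, the volume of the
thermally accessible step-parameter space), this module builds the per-step
series around a circular sequence with periodic boundary conditions,
averages it in sliding k-mer windows in the manner of a hydropathy plot, and
ranks windows by percentile.  High window scores flag regions soft enough to
bend sharply or wrap a protein; low scores flag rigid regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .sequences import CircularSequence, reverse_complement

ALL_TETRAMERS = ["".join(t) for t in product("ACGT", repeat=4)]


@dataclass
class TetramerTable:
    """Map from tetramer (4-mer over ACGT) to deformability value V_step.

    Values are positive reals in deg^3 A^3.  A table is *complete* when all
    256 tetramers resolve; reverse-complement symmetrization fills a
    tetramer from its reverse complement (a step read on the other strand is
    the same physical step).
    """

    entries: dict[str, float]
    metadata: str = ""

    def __post_init__(self) -> None:
        for t, v in self.entries.items():
            if len(t) != 4 or any(c not in "ACGT" for c in t):
                raise ValueError(f"bad tetramer key {t!r}")
            if not v > 0:
                raise ValueError(f"deformability value for {t} must be > 0, got {v}")

    @property
    def coverage(self) -> int:
        return len(self.entries)

    def is_complete(self) -> bool:
        return self.coverage == 256

    def symmetrized(self) -> "TetramerTable":
        """Close the table under reverse complement.

        Tetramers present on both strands must agree exactly; silent
        averaging of conflicting values would hide data errors, so a
        conflict raises.
        """
        out: dict[str, float] = {}
        for t, v in self.entries.items():
            rc = reverse_complement(t)
            for key in (t, rc):
                if key in out and out[key] != v:
                    raise ValueError(
                        f"conflicting values for reverse-complement pair "
                        f"{t}/{rc}: {out[key]} vs {v}"
                    )
                out[key] = v
        return TetramerTable(out, self.metadata)

    def value(self, tetramer: str) -> float:
        try:
            return self.entries[tetramer]
        except KeyError:
            raise KeyError(f"tetramer {tetramer} missing from table") from None


def load_table(path, symmetrize: bool = True, strict: bool = True) -> TetramerTable:
    """Load a tetramer deformability table from TSV/CSV with columns
    ``tetramer`` and ``value``.

    With ``symmetrize`` the table is closed under reverse complement
    (conflicts raise); with ``strict`` an incomplete table (< 256 tetramers
    after symmetrization) raises.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    if "tetramer" not in cols or "value" not in cols:
        raise ValueError("table must have columns 'tetramer' and 'value'")
    entries: dict[str, float] = {}
    for t, v in zip(df[cols["tetramer"]], df[cols["value"]]):
        t = str(t).upper()
        v = float(v)
        if t in entries and entries[t] != v:
            raise ValueError(f"duplicate tetramer {t} with conflicting values")
        entries[t] = v
    table = TetramerTable(entries, metadata=str(path))
    if symmetrize:
        table = table.symmetrized()
    if strict and not table.is_complete():
        raise ValueError(
            f"incomplete tetramer table: {table.coverage}/256 tetramers"
        )
    return table


def save_table(table: TetramerTable, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(
        {"tetramer": list(table.entries), "value": list(table.entries.values())}
    ).to_csv(path, sep=sep, index=False)


@dataclass
class StepSeries:
    """Per-base-pair-step deformability values.

    Step i (1-based) sits between base pairs i and i+1 (modulo L on a
    circle); a circular sequence of L base pairs has L steps, a linear one
    L - 1.
    """

    values: np.ndarray
    circular: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("step series must be a non-empty 1-D array")
        if not np.all(self.values > 0):
            raise ValueError("step values must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def step_values(seq: CircularSequence, table: TetramerTable) -> StepSeries:
    """Deformability value for every base-pair step of a circular sequence.

    The value of step i is the table entry for the tetramer at positions
    i-1 .. i+2 (modulo L): the step plus one flanking base pair on each
    side, the first flank being 5' on the reference strand.  Periodic
    boundary conditions supply the flanks across the origin.
    """
    if not seq.circular:
        raise ValueError("step_values requires a circular sequence (periodic context)")
    L = len(seq)
    if L < 4:
        raise ValueError("sequence must be at least 4 bp")
    if not table.is_complete():
        raise ValueError("tetramer table is incomplete; symmetrize or supply all 256")
    s = seq.residues
    tripled = s[-1] + s + s[:2]  # position i-1 .. i+2 for i = 1..L
    vals = np.empty(L)
    for i in range(L):
        vals[i] = table.value(tripled[i : i + 4])
    return StepSeries(vals, circular=True)


@dataclass
class KmerProfile:
    """Sliding k-mer deformability profile of a circular sequence.

    ``scores[c-1]`` is the mean of the k - 1 base-pair steps internal to the
    k-mer of base pairs centred on position c.  The window on centre c
    covers positions c - ceil(k/2) + 1 .. c + floor(k/2); for odd k that is
    the symmetric c +/- (k-1)/2.  ``baseline`` is the mean over all steps,
    the natural zero for "more/less deformable than average".
    """

    k: int
    scores: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return self.scores.size

    def score_at(self, center: int) -> float:
        """Score of the window centred on 1-based position ``center``."""
        return float(self.scores[(center - 1) % len(self.scores)])


def kmer_profile(series: StepSeries, k: int) -> KmerProfile:
    """Average the step series in sliding windows of k base pairs.

    A k-mer of base pairs contains k - 1 internal steps; windows wrap
    (periodic boundaries), giving one score per position.  Every step lands
    in exactly k - 1 windows, so the profile mean equals the series mean.
    """
    L = len(series)
    if not series.circular:
        raise ValueError("k-mer profiling requires a circular step series")
    if not 2 <= k <= L:
        raise ValueError(f"window length k={k} must satisfy 2 <= k <= L={L}")
    vals = series.values
    # window centred on c starts at base pair c - ceil(k/2) + 1 and holds
    # steps start .. start+k-2
    start_offset = -(-k // 2) - 1  # ceil(k/2) - 1
    doubled = np.concatenate([vals, vals])
    cum = np.concatenate([[0.0], np.cumsum(doubled)])
    scores = np.empty(L)
    for c in range(1, L + 1):
        a = (c - 1 - start_offset) % L  # 0-based first step index
        scores[c - 1] = (cum[a + k - 1] - cum[a]) / (k - 1)
    return KmerProfile(k=k, scores=scores, baseline=series.mean)


@dataclass(frozen=True)
class RegionRank:
    """Percentile statement for one window centre.

    ``top_fraction`` is the fraction of window scores strictly greater than
    the centre's score ("top X%"), ``bottom_fraction`` the fraction strictly
    less ("bottom X%"); ``ties`` counts windows with exactly this score
    (including the centre itself) and ``rank`` is 1 + number strictly
    greater.
    """

    center: int
    score: float
    rank: int
    ties: int
    top_fraction: float
    bottom_fraction: float


def rank_region(profile: KmerProfile, center: int) -> RegionRank:
    """Percentile rank of the window centred on a 1-based position."""
    score = profile.score_at(center)
    scores = profile.scores
    greater = int(np.sum(scores > score))
    less = int(np.sum(scores < score))
    ties = int(np.sum(scores == score))
    L = scores.size
    return RegionRank(
        center=center,
        score=score,
        rank=greater + 1,
        ties=ties,
        top_fraction=greater / L,
        bottom_fraction=less / L,
    )


def export_profile(profile: KmerProfile, path, plot: str | None = None) -> pd.DataFrame:
    """Write a profile as CSV (position, score, score_minus_baseline).

    ``plot`` optionally writes a circular heatmap-style polar figure of the
    profile, the natural display for a minicircle.
    """
    L = len(profile)
    df = pd.DataFrame(
        {
            "position": np.arange(1, L + 1),
            "score": profile.scores,
            "score_minus_baseline": profile.scores - profile.baseline,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    if plot is not None:
        plot_circular_profile(profile, plot)
    return df


def plot_circular_profile(profile: KmerProfile, path, cmap: str = "viridis") -> None:
    """Render the profile as a coloured ring on polar axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = len(profile)
    theta = np.linspace(0, 2 * np.pi, L, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    sc = ax.scatter(
        theta, np.ones(L), c=profile.scores, cmap=cmap, s=12, marker="s"
    )
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_yticks([])
    ax.set_xticks([])
    ax.set_ylim(0, 1.2)
    fig.colorbar(sc, ax=ax, shrink=0.7, label=f"{profile.k}-mer deformability score")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def read_profile(path) -> pd.DataFrame:
    """Round-trip reader for :func:`export_profile` CSVs."""
    return pd.read_csv(path)
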