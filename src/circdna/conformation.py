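"""Base-pair-step conformational classification and rigid-body geometry.

Double-helical DNA in protein complexes departs from canonical B-form
locally: stretches may adopt the underwound A form, the severely bent and
untwisted TA form first seen at TATA-box complexes, or melt entirely.  Two
phosphorus-based descriptors computed by standard nucleic-acid geometry
software separate these states: z_P, the mean out-of-plane z coordinate of
the backbone phosphorus atoms in the step frame (B: z_P <= 0.5 A, A: z_P >=
1.5 A), and z_P(h), the helical-axis projection of the inter-strand P-P
vector (TA: z_P(h) > 4 A).

The module also rebuilds 3-D base-pair frames from the six rigid-body step
parameters (Shift, Slide, Rise, Tilt, Roll, Twist) using the mid-step-triad
convention, and measures the superhelical handedness of the resulting axis:
inserting underwound A-like stretches into B-DNA writhes the axis into a
right-handed superhelix, overwound C-like stretches into a left-handed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STEP_PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
BP_PARAM_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")

# z_P thresholds (Angstrom)
ZP_B_MAX = 0.5
ZP_A_MIN = 1.5
ZPH_TA_MIN = 4.0


@dataclass(frozen=True)
class StepParameters:
    """Six rigid-body parameters of a base-pair step.

    Displacements (Shift, Slide, Rise) in Angstrom, expressed in the
    mid-step frame; rotations (Tilt, Roll, Twist) in degrees.
    """

    shift: float = 0.0
    slide: float = 0.0
    rise: float = 3.4
    tilt: float = 0.0
    roll: float = 0.0
    twist: float = 36.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite step parameter {f.name}={v}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)


@dataclass(frozen=True)
class BasePairParameters:
    """Six rigid-body parameters of one base pair (Shear, Stretch, Stagger
    in Angstrom; Buckle, Propeller, Opening in degrees)."""

    shear: float = 0.0
    stretch: float = 0.0
    stagger: float = 0.0
    buckle: float = 0.0
    propeller: float = 0.0
    opening: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite base-pair parameter {f.name}={v}")


@dataclass(frozen=True)
class StepDescriptor:
    """Per-step record as exported by nucleic-acid geometry software:
    optional z_P / z_P(h) descriptors plus optional step parameters."""

    zp: float | None = None
    zph: float | None = None
    step: StepParameters | None = None


def classify_zp(zp: float) -> str:
    """Classify a step as A-like, B-like or intermediate from z_P (A).

    B when z_P <= 0.5, A when z_P >= 1.5, intermediate in between.
    """
    if not math.isfinite(zp):
        raise ValueError(f"z_P must be finite, got {zp}")
    if zp <= ZP_B_MAX:
        return "B"
    if zp >= ZP_A_MIN:
        return "A"
    return "intermediate"


def classify_zph(zph: float) -> str:
    """Classify a step as B or TA from z_P(h) (A): TA when > 4, else B.

    The published thresholds are strict on both sides and leave exactly
    4 A unassigned; this implementation assigns the boundary to B.
    """
    if not math.isfinite(zph):
        raise ValueError(f"z_P(h) must be finite, got {zph}")
    return "TA" if zph > ZPH_TA_MIN else "B"


# Default acceptance intervals for calling a base pair intact.  These are
# package defaults spanning generously beyond values typical of paired bases
# in high-resolution structures; they are synthetic implementation defaults,
# not published reference ranges, and should be replaced by user-supplied
# intervals for quantitative work.
DEFAULT_MELTED_RANGES: dict[str, tuple[float, float]] = {
    "shear": (-2.0, 2.0),
    "stretch": (-2.0, 2.0),
    "stagger": (-2.5, 2.5),
    "buckle": (-35.0, 35.0),
    "propeller": (-35.0, 25.0),
    "opening": (-30.0, 30.0),
}


def is_melted(
    bp: BasePairParameters,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> bool:
    """True when any base-pair parameter falls outside its closed interval.

    ``ranges`` maps parameter name to (low, high); all six parameters must
    have a range.  Defaults to :data:`DEFAULT_MELTED_RANGES`.
    """
    if ranges is None:
        ranges = DEFAULT_MELTED_RANGES
    for name in BP_PARAM_NAMES:
        if name not in ranges:
            raise KeyError(f"no melted-pair range supplied for {name!r}")
        lo, hi = ranges[name]
        v = getattr(bp, name)
        if v < lo or v > hi:
            return True
    return False


@dataclass(frozen=True)
class Frame:
    """A base-pair coordinate frame: origin (A) and right-handed orthonormal
    triad whose columns are the frame's x, y, z axes in the lab frame."""

    origin: np.ndarray
    triad: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        triad = np.asarray(self.triad, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "triad", triad)
        if not np.allclose(triad.T @ triad, np.eye(3), atol=1e-9):
            raise ValueError("triad is not orthonormal")
        if np.linalg.det(triad) < 0:
            raise ValueError("triad is left-handed")


@dataclass
class HelixModel:
    """Rebuilt double-helix geometry: one frame per base pair."""

    frames: list[Frame]

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def origins(self) -> np.ndarray:
        return np.array([f.origin for f in self.frames])


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _step_transform(p: StepParameters) -> tuple[np.ndarray, np.ndarray]:
    """Relative rotation and mid-step triad (in the preceding frame) of one
    step, mid-step-triad convention.

    The tilt/roll bend is a single rotation of magnitude Gamma =
    sqrt(tilt^2 + roll^2) about an axis in the xy plane at phase phi =
    atan2(tilt, roll) from the roll (y) axis; twist is split half before,
    half after.  The displacement (shift, slide, rise) is expressed in the
    mid-step triad.
    """
    tilt = math.radians(p.tilt)
    roll = math.radians(p.roll)
    twist = math.radians(p.twist)
    gamma = math.hypot(tilt, roll)
    phi = math.atan2(tilt, roll) if gamma > 0 else 0.0
    rot = _rot_z(twist / 2 - phi) @ _rot_y(gamma) @ _rot_z(twist / 2 + phi)
    mid = _rot_z(twist / 2 - phi) @ _rot_y(gamma / 2) @ _rot_z(phi)
    return rot, mid


def rebuild(
    steps: Sequence[StepParameters], initial: Frame | None = None
) -> HelixModel:
    """Generate base-pair frames by sequential composition of step
    transforms.

    Frame 1 is the identity frame at the origin unless ``initial`` is
    given; each step then places frame i+1 relative to frame i.  A list of
    n steps yields n + 1 frames.
    """
    if not steps:
        raise ValueError("at least one step is required")
    if initial is None:
        initial = Frame(np.zeros(3), np.eye(3))
    frames = [initial]
    for p in steps:
        rot, mid = _step_transform(p)
        prev = frames[-1]
        mid_triad = prev.triad @ mid
        disp = mid_triad @ np.array([p.shift, p.slide, p.rise])
        frames.append(Frame(prev.origin + disp, prev.triad @ rot))
    return HelixModel(frames)


def step_parameters(frames: Sequence[Frame]) -> list[StepParameters]:
    """Recover step parameters from consecutive frames (inverse of
    :func:`rebuild`).

    Decomposes the relative rotation R1^T R2 as Rz(w/2 - phi) Ry(Gamma)
    Rz(w/2 + phi) and expresses the origin displacement in the mid-step
    triad.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    out = []
    for f1, f2 in zip(frames, frames[1:]):
        A = f1.triad.T @ f2.triad
        # ZYZ Euler angles: A = Rz(alpha) Ry(gamma) Rz(beta)
        cg = min(1.0, max(-1.0, A[2, 2]))
        gamma = math.acos(cg)
        if abs(gamma) < 1e-12:
            alpha = math.atan2(A[1, 0], A[0, 0]) / 2
            beta = alpha
        else:
            alpha = math.atan2(A[1, 2], A[0, 2])
            beta = math.atan2(A[2, 1], -A[2, 0])
        twist = alpha + beta
        phi = (beta - alpha) / 2
        # the (alpha, beta, gamma) and (alpha+pi, beta+pi, -gamma) branches
        # describe the same rotation; pick the one with twist in (-pi, pi]
        if twist > math.pi:
            twist -= 2 * math.pi
            gamma = -gamma
        elif twist <= -math.pi:
            twist += 2 * math.pi
            gamma = -gamma
        tilt = gamma * math.sin(phi)
        roll = gamma * math.cos(phi)
        params = StepParameters(
            tilt=math.degrees(tilt),
            roll=math.degrees(roll),
            twist=math.degrees(twist),
            shift=0.0,
            slide=0.0,
            rise=0.0,
        )
        _, mid = _step_transform(params)
        disp = (f1.triad @ mid).T @ (f2.origin - f1.origin)
        out.append(
            StepParameters(
                shift=disp[0],
                slide=disp[1],
                rise=disp[2],
                tilt=math.degrees(tilt),
                roll=math.degrees(roll),
                twist=math.degrees(twist),
            )
        )
    return out


# moving-average passes applied before measuring axis torsion; a single
# pass leaves enough double-helical ripple to corrupt the torsion sign when
# the window is mismatched to the local helical period, three passes
# (a piecewise-quadratic kernel) suppress it across windows of 8-12 bp
SMOOTH_PASSES = 3


def smooth_axis(origins: np.ndarray, window: int, passes: int = 1) -> np.ndarray:
    """Centred moving average of the origin polyline (valid windows only),
    optionally applied repeatedly for stronger ripple suppression."""
    origins = np.asarray(origins, dtype=float)
    kernel = np.ones(window) / window
    out = origins
    for _ in range(passes):
        n = out.shape[0]
        if window < 1 or window > n:
            raise ValueError(f"smoothing window {window} invalid for {n} points")
        out = np.column_stack(
            [np.convolve(out[:, j], kernel, mode="valid") for j in range(3)]
        )
    return out


def mean_axis_torsion(model: HelixModel, smooth_window: int = 10) -> float:
    """Mean discrete torsion sign of the smoothed helical axis.

    The base-pair origins are smoothed by ``SMOOTH_PASSES`` passes of a
    centred moving average of ``smooth_window`` base pairs (about one
    helical turn by default), unit tangents e_i are taken between
    successive smoothed points, and each interior point contributes
    chi_i = sign((e_{i-1} x e_i) . e_{i+1}).  A positive mean marks an
    axis tracing a right-handed space curve (positive torsion), a negative
    mean a left-handed one, ~0 a straight or planar axis.
    """
    if len(model) < 3 * smooth_window:
        raise ValueError(
            f"need >= {3 * smooth_window} frames for smoothing window {smooth_window}"
        )
    axis = smooth_axis(model.origins, smooth_window, passes=SMOOTH_PASSES)
    diffs = np.diff(axis, axis=0)
    norms = np.linalg.norm(diffs, axis=1)
    keep = norms > 1e-12
    tangents = diffs[keep] / norms[keep][:, None]
    if tangents.shape[0] < 3:
        return 0.0
    chi = []
    for i in range(1, tangents.shape[0] - 1):
        triple = float(
            np.dot(np.cross(tangents[i - 1], tangents[i]), tangents[i + 1])
        )
        chi.append(0.0 if abs(triple) < 1e-12 else math.copysign(1.0, triple))
    return float(np.mean(chi)) if chi else 0.0


def handedness(
    model: HelixModel, smooth_window: int = 10, tau_min: float = 1e-3
) -> str:
    """Superhelical handedness of a rebuilt axis: 'right', 'left' or 'none'.

    Handedness follows the supercoiling naming convention, under which the
    superhelix produced by underwound (A-like) insertions is the
    right-handed, negative one: the solenoidal axis such insertions trace
    has *negative* discrete torsion, so 'right' is returned when the mean
    axis torsion is below -tau_min and 'left' when above +tau_min.
    'none' (straight or planar axis) otherwise.
    """
    tau = mean_axis_torsion(model, smooth_window)
    if tau < -tau_min:
        return "right"
    if tau > tau_min:
        return "left"
    return "none"


# Step-parameter presets for the canonical helix forms used in the
# superhelix demonstrations: ideal B, underwound A-like and overwound
# C-like steps (Shift, Slide, Rise, Tilt, Roll, Twist).
PRESET_STEPS: dict[str, StepParameters] = {
    "B": StepParameters(0.0, 0.0, 3.4, 0.0, 0.0, 36.0),
    "A": StepParameters(0.0, -2.0, 3.4, 0.0, 12.0, 34.0),
    "C": StepParameters(0.0, 2.0, 3.4, 0.0, -12.0, 38.298),
}


def alternating_block_steps(
    n_bp: int = 55, block: int = 5, forms: tuple[str, str] = ("B", "A")
) -> list[StepParameters]:
    """Step list for a chain of ``n_bp`` base pairs made of alternating
    ``block``-bp stretches of two helix forms (steps inherit the form of
    the block containing their 5' base pair)."""
    if n_bp < 2:
        raise ValueError("need at least 2 base pairs")
    steps = []
    for i in range(n_bp - 1):
        form = forms[(i // block) % 2]
        steps.append(PRESET_STEPS[form])
    return steps


_COLUMN_ALIASES = {
    "shift": "shift",
    "slide": "slide",
    "rise": "rise",
    "tilt": "tilt",
    "roll": "roll",
    "twist": "twist",
    "zp": "zp",
    "z_p": "zp",
    "zph": "zph",
    "z_p_h": "zph",
    "zp_h": "zph",
    "zp(h)": "zph",
}


def read_step_table(path, require_params: bool = False) -> list[StepDescriptor]:
    """Read a per-step CSV export (3DNA/DSSR-style columns) into
    :class:`StepDescriptor` records, preserving row order.

    Recognised columns (case-insensitive): the six step parameters and
    z_P / z_P(h) under common spellings.  With ``require_params`` all six
    step-parameter columns must be present.
    """
    df = pd.read_csv(path)
    colmap = {}
    for c in df.columns:
        key = c.strip().lower().replace(" ", "")
        if key in _COLUMN_ALIASES:
            colmap[_COLUMN_ALIASES[key]] = c
    if require_params:
        missing = [n for n in STEP_PARAM_NAMES if n not in colmap]
        if missing:
            raise ValueError(f"step table missing required column(s): {', '.join(missing)}")
    has_params = all(n in colmap for n in STEP_PARAM_NAMES)
    out = []
    for _, row in df.iterrows():
        step = None
        if has_params:
            vals = {}
            for n in STEP_PARAM_NAMES:
                v = row[colmap[n]]
                if not np.isfinite(float(v)):
                    raise ValueError(f"non-numeric {n} value {v!r}")
                vals[n] = float(v)
            step = StepParameters(**vals)
        zp = float(row[colmap["zp"]]) if "zp" in colmap else None
        zph = float(row[colmap["zph"]]) if "zph" in colmap else None
        out.append(StepDescriptor(zp=zp, zph=zph, step=step))
    return out


def write_step_table(descriptors: Iterable[StepDescriptor], path) -> None:
    """Write descriptors back to CSV (inverse of :func:`read_step_table`)."""
    rows = []
    for d in descriptors:
        row: dict[str, float] = {}
        if d.step is not None:
            for n in STEP_PARAM_NAMES:
                row[n] = getattr(d.step, n)
        if d.zp is not None:
            row["zp"] = d.zp
        if d.zph is not None:
            row["zph"] = d.zph
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_axis_pdb(model: HelixModel, path) -> None:
    """Write one pseudo-atom per base-pair origin as a PDB file, so the
    rebuilt axis can be inspected in any molecular viewer."""
    with open(path, "w") as fh:
        for i, f in enumerate(model.frames, start=1):
            x, y, z = f.origin
            fh.write(
                f"ATOM  {i:5d}  P   BP  A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P\n"
            )
        fh.write("END\n")
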