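# Methods

This note documents the models and procedures `circdna` implements, the
conventions it commits to where several are defensible, and what its
synthetic-data tests do and do not establish about real data.

## Coordinates and topology

All positions are 1-based and inclusive. On a circular sequence of length
L, position L is followed by position 1, intervals with start > end wrap
through the origin, and every windowed computation uses periodic boundary
conditions. A linear sequence simply forbids wrapping. FASTA input carries
topology either as a `circular=true` keyword in the header or as an
explicit flag.

## Purine/pyrimidine register mapping

A density-derived profile is a string over {R, Y, X}: R for bases whose
density shows the two-ring purine shape, Y for the single-ring pyrimidine
shape, X for unresolvable density. A sequence-derived profile maps A,G → R
and C,T → Y and never contains X.

**Scanning.** The profile is compared at every start position of the
circular reference (L offsets) on both strands. The reverse strand is
searched by reversing and R/Y-complementing the profile and comparing it
against the forward reference, so all reported coordinates are
forward-strand positions of the 5′-most aligned base. An X is compatible
with either base class but spends the same tolerance budget as a mismatch:
a hit is reported when n_mismatch + n_unresolved ≤ max_free. Hits are
sorted by spent budget then position; the scan result's `unique` flag is
true when exactly one hit attains the minimum, the condition under which a
register assignment is trustworthy. All minimal hits are always reported —
ties are never silently dropped.

**Match probability.** Under a null model in which each position of a
random duplex is independently R or Y with probability ½, the probability
that a fixed n-symbol profile matches with at most f free positions is
P(n, f) = 2⁻ⁿ Σ_{i≤f} C(n, i), evaluated in exact integer arithmetic. The
"1 in N" form rounds the exact reciprocal 2ⁿ/Σ C(n,i) to the nearest
integer; this reproduces both 55,738 (n=24, f=2) and 2,304,167 (n=30,
f=2). The null ignores base-composition bias and dinucleotide correlation
in real sequences; it is a calibration of surprise, not a sequence model.

**Palindromes.** A hit is a maximal even-length substring equal to its own
reverse complement, found by expanding around each of the L inter-base-pair
centres; maximality (not extensible by one base on both sides) is automatic
per centre. On circles, arms are capped at L/2 so a hit never overlaps
itself, and wrap-spanning hits are reported once in start > end notation.

## Deformability profiling

Each base-pair step is assigned the value V_step (deg³·Å³) of its tetramer
context — the step plus one flanking base pair on each side, read 5′→3′ on
the reference strand, so step i (between base pairs i and i+1) uses
positions i−1…i+2 modulo L. Tables load from two-column TSV/CSV and are
closed under reverse complement; a strand-symmetric pair carrying
conflicting values is an error rather than being averaged, because silent
averaging hides transcription mistakes. Strict loading requires all 256
tetramers.

The k-mer score at centre c is the mean of the k − 1 steps internal to the
k-bp window on c. The window spans c − ⌈k/2⌉ + 1 … c + ⌊k/2⌋: symmetric
(c ± (k−1)/2) for odd k, and for even k the extra position sits 5′ of the
centre. This centering makes the k = 2 profile coincide exactly with the
step series. Because every step falls in exactly k − 1 circular windows,
the profile mean equals the series mean (the "baseline"), and rotating the
input sequence rotates the profile exactly.

Percentiles use strict comparison: "top X%" is the fraction of window
scores strictly greater than the queried score, "bottom X%" strictly less,
with the tie count reported separately, so a uniform profile is
simultaneously top 0% and bottom 0% with L ties.

These window scores describe the average softness of the steps inside a
window, not the elastic response of the k-mer as a mechanical unit; the
averaging damps extremes at both ends of the scale.

## Step conformation and rebuilt geometry

z_P (mean out-of-plane z of the backbone phosphorus atoms in the step
frame) classifies a step as B (≤ 0.5 Å), A (≥ 1.5 Å) or intermediate;
z_P(h) (helical-axis projection of the inter-strand P–P vector) separates
TA (> 4 Å) from B, with the unassigned boundary value 4 Å mapped to B.
Overwound C-like character is representable in rebuild presets but is
never emitted by classification. Both descriptors are consumed from
per-step CSV exports of standard nucleic-acid geometry software; computing
them from atomic coordinates is out of scope.

A base pair is called melted when any of Shear, Stretch, Stagger (Å) or
Buckle, Propeller, Opening (°) leaves its closed acceptance interval. The
shipped intervals (±2, ±2, ±2.5 Å; ±35, −35…25, ±30°) are package
defaults chosen to bracket values typical of intact pairs in
high-resolution structures; quantitative work should supply its own
intervals via config.

**Rebuild.** Frames are generated by the mid-step-triad (CEHS) convention.
With Γ = √(Tilt² + Roll²), φ = atan2(Tilt, Roll) and ω = Twist, the
relative rotation is R = R_z(ω/2 − φ)·R_y(Γ)·R_z(ω/2 + φ) and the origin
advances by the mid-step triad R_z(ω/2 − φ)·R_y(Γ/2)·R_z(φ) applied to
(Shift, Slide, Rise). The inverse (parameter extraction from consecutive
frames) uses the ZYZ Euler decomposition, normalising Twist into
(−180°, 180°] by the branch symmetry (α, β, Γ) ↔ (α+π, β+π, −Γ);
round-trip recovery is exact to 1e−8 over random step lists, checked
against an independent scipy-based decomposition.

**Handedness.** The base-pair origins are smoothed by three passes of a
centred moving average of `smooth_window` (default 10 bp ≈ one helical
turn); a single pass leaves enough double-helical ripple to corrupt the
torsion sign when the window is mismatched to the local helical period,
while three passes (a piecewise-quadratic kernel) give a stable sign for
windows of 8–12 bp on the 55-bp demonstration chains. Unit tangents e_i of
the smoothed axis then yield discrete torsion signs
χ_i = sign((e_{i−1} × e_i)·e_{i+1}), and the mean χ is compared with
±τ_min (default 10⁻³).

Naming follows supercoiling convention rather than raw curve torsion: the
solenoidal axis traced by interspersed *underwound* A-like stretches has
negative discrete torsion, and that superhelix is the right-handed
(negative) one; so mean torsion < −τ_min reports "right", > +τ_min
reports "left", and a straight or planar axis reports "none". The
geometric sign itself was cross-checked by a screw decomposition of the
periodic construction's repeat transform, which gives the same chirality
as the smoothed-axis torsion.

The demonstration chains are 55 bp with alternating 5-bp blocks of ideal
B (0, 0, 3.4 Å, 0, 0, 36°) and either A-like (0, −2.0, 3.4, 0, 12, 34) or
C-like (0, 2.0, 3.4, 0, −12, 38.298) steps; uniform B gives a straight
axis and handedness "none".

## Motif scanning

Scores are plain additive lookups of the supplied 4×W weight matrix —
no background correction or log transform — since distributed gyrase-motif
matrices already define sign (positive = fits the motif); users may
pre-transform weights if they need log-odds. The PWM centre column
(⌈W/2⌉, i.e. even widths round toward 5′) is aligned to the stated
reference position; the reverse strand scores the reverse complement of
the same forward window. The 130-column motif splits into first+core
(83), core (36) and core+second (83) sub-matrices with columns copied
verbatim. The ±radius positivity query (default 5 bp) is inclusive at
both ends and uses circular distance.

## Synthetic data: what it emulates and what it does not

Generators are deterministic in their seed. `synth_sequence` draws i.i.d.
bases at a requested GC fraction (default 0.5, length 601 bp to mirror the
minicircle substrate) and can plant a nucleotide realisation of an R/Y
profile at a known position; `planted_query` degrades the planted truth
with an exact number of miscalls and unresolved X's, emulating
density-quality defects. `synth_table` fills all 256 tetramers with
strand-symmetric values uniform on [1, 8] deg³·Å³, bracketing the few-unit
scale of published step deformabilities; `synth_pwm` builds matrices whose
per-column maximum is a known consensus.

Passing tests on these inputs establish that the algorithms are correct
(oracle-equivalent, equivariant, exactly recovering plants) — not that
real minicircle analyses are reproduced. Real sequences are not i.i.d.,
real deformability tables have strongly non-uniform structure (e.g.
pyrimidine–purine steps far softer than average), and real PWMs encode
periodicity the synthetic ones do not. Analyses of the published
minicircle require the externally distributed 601-bp sequence, tetramer
deformability table and gyrase-motif matrix as user-supplied inputs.

## Problem sizes and defaults

Test and demonstration sizes are chosen to exercise every code path at
interactive speed: 601-bp circles for scanning and profiling (matching the
minicircle), ≤ 64-bp instances for brute-force oracle comparisons, 200
replicates for recovery and hit-rate statistics, 55-bp chains for the
handedness demonstration. Defaults: max_free 2 (one miscall + one
unresolved base, the worst case in the shipped assignment tables), k = 35
(G-segment length; 49 for the wrap), smooth_window 10, τ_min 10⁻³,
palindrome min_len 4, motif radius 5.

## Known limitations

- Scanning is O(L·n) per strand — ample for minicircles, not tuned for
  genomes.
- The match-probability null ignores composition bias; odds on GC-skewed
  references are approximate.
- Handedness is a global sign; chains mixing senses along their length
  yield whichever dominates the mean, and chains shorter than
  3·smooth_window are rejected rather than guessed at.
- Melted-pair defaults are generic; they are not fitted reference
  intervals.
- The wrap-around numbering of alignments crossing the origin uses
  start > end notation; downstream tools must honour it.
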