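# Methods

This note records the models, conventions and numerical choices behind
`origametry`, in the spirit of a simulation package's model
documentation.  Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Coarse-grained data model and units

A nucleotide is a rigid body: a position, a base versor `a1` (backbone →
base face) and a stacking versor `a3`.  Files use the oxDNA-style text
formats with the simulation length unit; internally everything is in
nanometres, converted only at the I/O boundary with the single constant
0.8518 nm per unit.  Velocities and angular velocities are parsed and
round-tripped but never interpreted.  Both header orders of the
configuration format are tolerated on read because the two common file
dialects order the `t`/`b`/`E` lines differently.

### Idealized helix geometry

Builders and generators place base pairs with rise 0.34 nm/bp and pitch
10.5 bp/turn (the untwisted-origami convention).  Backbone sites sit on
a 0.6 nm-radius cylinder; the nucleotide position and the base
interaction site lie 0.3407 nm (0.4 length units) inward of the
backbone along `a1`.  Consequently nucleotide centres sit at ~0.26 nm
radius and the two base sites of a pair end up ~0.16 nm apart, well
inside the base-pair detection cutoff.  Placing the *positions*
themselves at 0.6 nm would be inconsistent with the fixed base-site
offset and the 0.45 nm pairing cutoff (the sites would be 0.52 nm
apart), so 0.6 nm is interpreted as the backbone-site radius.

### Geometric base pairing

A pair requires: base-site distance < 0.45 nm, anti-aligned stacking
versors (`a3_i · a3_j < -0.7`), mutually facing base versors, different
strands (or > 3 bases apart along one strand), and Watson–Crick
complementarity when base identities are informative.  Assignment is
greedy by ascending site distance with ties broken by lowest index.
This is a permissive geometric proxy for hydrogen bonding — no energy
function is evaluated — and both thresholds are configurable.

## Junction angles

A stacked four-way junction is treated as two quasi-continuous duplexes
(arms A+B and C+D) joined by two exchanging strands (B→C and D→A).  Arm
axes are least-squares lines through base-pair midpoints, skipping the
2 pairs nearest the junction and fitting the next 8 (16-bp arms leave a
comfortable margin; both numbers are parameters).  The axis is oriented
away from the junction.

* **Junction plane** — passes through the crossover-flanking
  nucleotides of the exchanging strands; its normal is the unit vector
  from duplex 1's junction end to duplex 2's, i.e. the plane is the
  mid-plane separating the two stacked duplexes.
* **φ (twist)** — signed angle, right-hand rule about that normal, from
  duplex 1's strand-travel direction to duplex 2's, measured once with
  the outgoing arm pair (φ₁) and once with the incoming pair (φ₂), then
  circularly averaged and mapped to [0°, 360°).  Ideal parallel and
  anti-parallel constructions measure exactly 0° and 180°, and a
  construct's mirror image measures 360° − φ (the handedness
  convention: left-handed < 180°).
* **θ (splay)** — per arm, the elevation above the junction plane
  signed positive *away from the partner duplex*; θ₁/θ₂ average the two
  arms of each duplex and θ averages those.  With this sign, a junction
  whose helices bend apart — the motif that produces the weave — has
  θ > 0 for all four arms.  θ so defined measures an achiral splay and
  is unchanged by mirroring (mirroring flips φ's chirality instead).
  An alternative convention signs every arm against one global normal;
  it flips under mirroring but cancels the splay of the two duplexes to
  zero, which would disconnect θ from the weave analysis, so it was not
  adopted.
* **Isomers** — arms are coaxially stacked when their outward axes have
  dot product < −0.8; the labeled stacking gives isomer I, either
  alternative pairing gives II, otherwise "open".  Frames whose
  crossover-flanking base pairs differ from the design pairing (branch
  migration) can be masked out before landscape accumulation.

All φ arithmetic is circular; θ is treated as linear.

## Umbrella windows and WHAM

The bias is harmonic in φ, `E = ½ k d(φ, c)²` in kT with `d` the minimal
circular difference in degrees.  Landscapes are accumulated on a
2°(φ) × 1°(θ) grid by default and unbiased with the standard
self-consistent histogram iteration (window offsets iterated to 1e-7,
at most 1e5 sweeps, log-space throughout).  Two numerical details
matter in practice:

* the per-window bias is Boltzmann-averaged over each φ bin rather than
  evaluated at the bin centre — far from a window's centre the harmonic
  bias changes by more than 1 kT across a 2° bin, and the centre-point
  approximation visibly biases F there;
* the reported minimum ignores bins with fewer than 5 raw samples (a
  lone tail sample reweighted out of a distant window can carry a
  spuriously low F) and can optionally be refined by a count-weighted
  quadratic fit around the raw argmin, because near a smooth minimum
  the per-bin statistical noise (≈ 1/√counts kT) exceeds the sub-kT
  curvature and makes the raw argmin wander by a few bins.

F is shifted so its occupied minimum is 0; `norm_offset` records the
constant that renormalizes exp(−F) to a probability.  Unoccupied bins
are flagged, never zero-filled, and non-overlapping windows raise a
warning plus a `disconnected` flag.  Temperature (default 296.15 K)
labels the kT unit only.  Marginal profiles sum Boltzmann weights over
the other axis, optionally restricted to a sub-range (e.g. the θ
profile for 160° ≤ φ ≤ 180°).

The WHAM recovery experiment in the tests draws 5×10⁴ samples from a
Gaussian density (φ: 120° ± 15°, θ: 0° ± 5°) through 12 windows at
92.5°–147.5° in 5° steps with k = 0.1 kT/deg², and accumulates θ at 2°
resolution; these settings put ≳100 samples in a couple of hundred
bins, which keeps the per-bin sampling noise (σ_F ≈ 1/√counts ≈ 0.1 kT
at the threshold) commensurate with the 0.3 kT comparison tolerance.

## Weave and corrugation

Helix axes are the per-base-pair midpoints of the two nucleotide
positions; frayed or melted positions (design pairs absent from a
frame's detected pairing) propagate as masked gaps, and helices with
fewer than 4 valid positions are dropped with a warning.  Weave
profiles are per-index means and standard deviations over frames of the
Euclidean distance between registered axis points of adjacent helices;
registration uses the design (or generator) base-pair index.

Waveform statistics locate extrema on a 3-point moving average (to
suppress jitter without shifting extrema) but take the amplitude from
the *raw* values at those locations — the smoothing would otherwise
clip a triangular wave's peaks by 2/3 of one per-bp step.  The dominant
period is the smallest lag attaining the circular autocorrelation peak
(a pure wave of period p scores equally at p, 2p, …).  Profiles with no
interior extrema are flagged aperiodic.

Corrugation follows the inter-helix vector around each junction: the
local vector and the junction-averaged vector (offsets −1…+1) are
projected onto the plane perpendicular to the average helix axis at the
junction (mean central-difference tangent of both helices, oriented
along increasing index), and the angle between the projections is
signed by the scalar triple product with that axis.  Axis points are
averaged over frames first.  By default only junctions with the
canonical neighbour pattern enter the mean curve — edge junctions, the
seam and seam-adjacent junctions are excluded, and the exclusion lists
are explicit flags on each junction record.

The closed-form splay estimate `triangular_theta(A, n, rise) =
atan((A/2)/(n·rise))` converts a perfectly triangular weave of
amplitude A and half-period n into the per-helix deflection angle; for
A = 1.5 nm, n = 16 bp, rise = 0.34 nm/bp it gives 7.85°.

## Mean structures, RMSD, helicity

Superposition is the closed-form least-squares rotation (SVD with the
determinant sign fixed to +1 — reflections would invert molecular
chirality).  Nearly collinear point sets warn but still return the
optimum.  The mean structure aligns every frame to the running mean
(initialized from frame 0), averages positions and versors,
re-orthonormalizes (`a3` normalized first, `a1` projected perpendicular
and normalized — arithmetic averaging is adequate for the small
fluctuations this package targets), and iterates to 1e-6 nm or 20
rounds; the per-nucleotide RMS spread is reported.  RMSD superposes
first and also returns per-point displacement vectors.  The default
RMSD point set for origami comparisons is helix-axis points; full
nucleotide sets work identically.

Helix-path helicity subtracts a `window`-point moving average from the
axis polyline, tracks the residual's winding angle in a fixed frame
perpendicular to the mean tangent, and fits the unwrapped angle
linearly: positive winding per step is right-handed (the B-DNA sense),
the period is 360° over the |slope|, and paths whose in-plane residual
RMS is below `noise_floor` (default 0.05 nm) report "none".

## caDNAno import and relaxation

caDNAno v2 JSON is parsed with full cross-reference validation;
caDNAno v3 is rejected explicitly.  The lattice is taken from the file
when declared, otherwise inferred: designs violating the honeycomb
(row+col) parity convention are treated as square, and an explicit
override always wins.  Crossovers are deduplicated per inter-helix
link, labeled `scaffold-seam` when the scaffold exchanges, and paired
into double crossovers when two links join the same helix pair within
2 bp.

`build_initial` walks scaffold and staple routing into strands (cycles
become circular strands; branching raises an error), emits one
nucleotide per occupied channel slot — skips omit the slot's
nucleotide, a loop of n inserts n extra nucleotides at fractional axial
offsets — and places everything at ideal B-form positions on the
lattice (2.5 nm spacing by default).  Scaffold bases come from a
supplied sequence or a seeded draw recorded in the call; staples
complement the scaffold wherever paired.

The initial geometry is locally pathological at crossovers and
insertions, so `relax` runs a capped-displacement steepest descent on a
surrogate energy: harmonic springs on backbone links plus a soft
quadratic repulsion between non-bonded nucleotides closer than 0.6 nm.
The spring rest length defaults to the ideal B-form backbone spacing
implied by the geometry parameters (~0.37 nm between nucleotide
positions), which makes an ideal duplex a fixed point of the descent; a
fixed value can be supplied instead.  Steps are capped at 0.05 nm per
nucleotide, energy-increasing steps are retried at half step (the
energy trace is monotone non-increasing), and iteration stops when the
largest backbone deviation falls below 0.1 nm or after 5000 steps.
This surrogate is a declared stand-in for a full force-field
minimization: it removes stretched bonds and overlaps, nothing more.

## Synthetic generators

The generators produce the statistical structure the analyses assume,
with every construction parameter recorded as ground truth (centerlines,
crossover indices, drawn angles, group labels) and full determinism per
seed.

* **Duplex** — ideal B-form, complementary antiparallel strands; bp i
  pairs nucleotides (i, 2n−1−i).
* **Junction ensemble** — (φ, θ) pairs are drawn from a stated density
  (separable Gaussians sample φ by inverse transform on a 0.02° grid,
  including the harmonic window reweighting; arbitrary densities fall
  back to rejection sampling) and each draw is realized *exactly* by a
  forward construction: two duplex stacks separated by 2 nm, directions
  at ±φ/2 about the separation axis, arms tilted by θ away from the
  partner stack, and the four strands routed so two cross between the
  stacks.  Arm sequences are random and non-repetitive, so the designed
  pairing is unambiguous (no branch migration).
* **Tile** — parallel helices whose in-plane displacement follows a
  triangular wave (period = junction spacing, adjacent pairs' crossover
  phases offset by half a period), giving inter-helix distances with
  full amplitude A, minima at crossovers and two symmetry groups of
  pairs.  A corrugation twist of 2δ adds an out-of-plane waveform sized
  so the measured inter-helix-vector rotation peaks at exactly ±δ a
  quarter period from each junction and returns to zero at the
  midpoint.  `seam=True` removes the central group-0 crossover, so that
  group opens wide there while the other group's nearby junctions are
  flagged seam-adjacent.
* **Bundle** — square lattice; each helix is deflected toward its four
  neighbours in turn with triangular bumps staggered by quarter
  periods, so interior centerlines wind once per junction-spacing
  cycle; the deflection order sets the handedness.

Noise is iid isotropic Gaussian applied per base pair and frame: both
nucleotides of a pair share the displacement, so helix-axis points
carry the full σ (the inter-helix distance spread is then √2·σ) and
base pairing is unaffected.  Versors are noise-free.  This emulates the
*location* statistics of thermal fluctuation but none of its
correlations: real trajectories have correlated, wavelength-dependent
fluctuations, sequence effects and occasional unbinding, so passing
round-trip tests demonstrates that the estimators are correct and
unbiased on the stated model, not that the model reproduces simulation
physics.  Quantities that require a force field (absolute landscape
positions, solvent-dependent spacings, fluctuation spectra) are out of
scope by construction.

## Default problem sizes

The test suite and acceptance script run at desk scale: tiles of 4–8
helices × 64–128 bp, bundles of 3×3–4×4 × 128–160 bp, junction
ensembles of ≤ 16-bp arms, 5×10⁴ WHAM samples, 200–500 noisy frames for
the statistical recoveries.  These sizes put every statistical check
comfortably inside its tolerance while keeping the whole suite in the
seconds-to-minutes range.
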