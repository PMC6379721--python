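# origametry

Structural analysis of coarse-grained DNA origami models.

DNA origami folds a long viral "scaffold" strand into a designed shape by
hundreds of short "staple" strands.  The staples pin neighbouring double
helices together at four-way (Holliday) junctions, and the mechanics of
those junctions leave characteristic fingerprints in the assembled
structure: a periodic **weave** in the inter-helix distance of 2D sheets,
a weak out-of-plane **corrugation** from the junctions' chiral twist
preference, and faint helical winding of helix paths in 3D bundles.
`origametry` quantifies these fingerprints from coarse-grained
(oxDNA-style) configurations and trajectories, whether produced by a
simulation engine or by the package's own seeded generators.

## What it computes

* **Junction geometry** — for a stacked four-way junction, the twist
  angle φ (0° = parallel, 180° = anti-parallel, φ < 180° left-handed)
  and the splay angle θ between the arms and the junction plane, from
  least-squares arm axes through base-pair midpoints; stacking-isomer
  classification; harmonic umbrella windows in φ and a WHAM
  (weighted-histogram) unbiasing into a free-energy landscape
  F(φ, θ) in kT with 1D marginal profiles, including profiles
  restricted to a φ subregion such as 160°–180°.
* **Weave and corrugation** — helix axes as base-pair midpoints,
  per-index inter-helix distance means and standard deviations,
  triangular-waveform statistics (amplitude, dominant period, extrema),
  the closed-form splay estimate
  θ = atan((A/2)/(n·rise)) for a triangular weave of amplitude A and
  half-period n, and signed corrugation-angle profiles around junctions.
* **Structure comparison** — Kabsch superposition (proper rotations
  only), iteratively aligned trajectory mean structures, RMSD with
  per-point displacement vectors, and helix-path helicity (handedness
  and period of the winding residual).
* **caDNAno import** — caDNAno v2 JSON parsing, crossover/seam
  detection, ideal B-form initial-configuration construction (skips,
  loops, scaffold/staple routing), and a capped-displacement surrogate
  relaxation to remove pathological initial geometry.
* **Synthetic data** — seeded generators for ideal duplexes, junction
  ensembles drawn from a stated (φ, θ) Boltzmann density, weave /
  corrugation tiles and square-lattice bundles, each carrying ground
  truth for validation.

## Worked example

```python
import numpy as np
from origametry import origami_metrics as om, synthetic_data as sd

# an 8-helix tile with a 1.5 nm triangular weave, crossovers every 32 bp
topo, traj, gt = sd.make_tile(n_helices=8, bp_per_helix=96,
                              junction_spacing=32, weave_amplitude=1.5,
                              seed=0)
axes = om.trajectory_axes(traj, gt.helix_pairs)
profile = om.weave_profile(axes, [("1", "2")])[0]
stats = om.weave_waveform_stats(profile.mean)
print(f"amplitude {stats.amplitude:.2f} nm, period {stats.period_bp:.0f} bp")
theta = om.triangular_theta(stats.amplitude, stats.period_bp / 2, rise=0.34)
print(f"implied junction splay theta = {theta:.2f} deg")
```

prints

```
amplitude 1.50 nm, period 32 bp
implied junction splay theta = 7.85 deg
```

i.e. the measured weave has the designed 1.5 nm amplitude and 32-bp
periodicity, and a perfectly triangular waveform of that size implies
each helix splays by 7.85° at the junctions — the same number the
closed form gives for a 1.5 nm / 16-bp triangular wave at 0.34 nm/bp.

The command line mirrors the library:

```sh
origametry synth tile --out-prefix tile --seed 0
origametry weave tile.traj tile.top --meta tile.meta.json --out weave.tsv
origametry convert design.json --out-prefix origami --relax
```

## Scope

The package analyzes configurations; it does not contain a force field,
thermostat or MD engine, and quantities that require large-scale
molecular dynamics or external experimental structures (absolute
landscape positions of a simulated junction, solvent-dependent
inter-helix spacings, RMSD against a cryo-EM model) are outside its
remit — though the same operations apply unchanged to externally
produced trajectories.
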