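# Methods

## Model

The nucleus is modelled as a melt of coarse-grained chromosome polymers
confined in a deformable spherical shell, evolved by Langevin dynamics in
implicit solvent. Everything is expressed in reduced units: bead diameter σ,
thermal energy kT, intrinsic time τ; one chromatin bead corresponds to 40 kb.

### Chromosomes

Each chromosome is a linear triblock copolymer. At full scale a chain has
6002 beads: one telomere (T) bead at each terminus, a contiguous block of
1000 constitutive-heterochromatin (C) beads at one end, and 5000 compartment
beads tiled with alternating euchromatin (E) / facultative-heterochromatin (F)
blocks. Block lengths are geometrically distributed with a configurable mean
(default 40 beads at full scale), and the per-type means are tuned so the
realized F fraction of the compartment region equals the requested *f*
(default 0.5) to the bead. The 6002-bead total fixes the telomere count
at two per chain — one per end; annotations can also be supplied as a
BED-like 4-column text file (chain, start bead, end bead, type).

### Interactions

Nonbonded pairs interact through a truncated-and-shifted 12-6 Lennard-Jones
potential. The raw epsilon is rescaled by 1/(1 + φ(r_c)) so that the *shifted*
well depth equals the tabulated affinity u_XY in kT exactly — this makes the
affinity matrix directly interpretable and the potential-minimum energy
testable without cutoff corrections. Attractive pairs are cut at 2.5σ;
repulsive-only pairs use the WCA form (cut at the potential minimum,
excluded-volume scale 1 kT). The conventional table is

| u (kT) | E | F | C | T | S |
|---|---|---|---|---|---|
| E | 0.05 | 0.15 | 0.30 | rep | rep |
| F | | 0.50 | 1.00 | rep | 0.75 |
| C | | | 1.50 | rep | 0.75 |
| T | | | | rep | 2.20 |
| S | | | | | rep |

Only the ordering u_TS > u_CC > u_FC > u_HS > u_FF > u_EC > u_EF > u_EE and
the two anchors (u_TS = 2.20, u_EE = 0.05) are fixed constraints of the model; the
intermediate values are package defaults chosen to satisfy the ordering with
roughly geometric spacing, and every entry is configurable. Telomeres interact
only sterically with chromatin, and adhere strongly to the shell (u_TS).
Halving all attractions preserves the ordering (asserted as a table property).

Bonds are finite-extensible springs,
U(r) = −½ k Δ² ln(1 − ((r−r₀)/Δ)²):

- **backbone / crosslink**: r₀ = 0, Δ = 1.5σ, k = 30 kT/σ² — the standard
  Kremer–Grest FENE spring; combined with excluded volume this forbids chain
  crossing.
- **shell**: r₀ = per-bond rest length, Δ = 0.6·r₀, k = 300 kT/σ². The form
  places the minimum at the prescribed rest length (a plain FENE cannot) and
  diverges at r₀ ± Δ. The high stiffness makes shell bonds effectively
  non-extensible: at k = 30 kT/σ² thermal bond compression lets the relaxed
  shell contract ≈8 percentage points past its rest geometry, whereas at
  300 kT/σ² the relaxed radius tracks the rest-length scaling (shrinkage
  ≈33% for a rest factor of 0.7). The stiff-shell variant multiplies k by 4
  and changes nothing else.

### Shell construction

Shell beads are placed randomly on a sphere of radius R₀ (42σ at full scale)
and spread to quasi-uniform coverage by a short repulsive relaxation
constrained to the surface. Bonds join all pairs within 1.5× the mean spacing;
degrees are then repaired into the interval [5, 8] (add the nearest unbonded
neighbor below degree 5; drop the longest bond above degree 8, preferring
partners that stay above 5). Bead and bond counts are fixed afterwards. Rest
lengths are 0.7× the construction lengths, so the relaxed shell contracts by
roughly 30%, and because uniform scaling by 0.7 satisfies every rest length
simultaneously, the contracted shell is stress-free.

The bead count defaults to a construction spacing of 1.714σ
(n ≈ 4.94·R₀², i.e. ≈8700 at full scale and 968 at the reduced scale).
This density is chosen so that (a) the contracted shell (spacing ≈1.2σ) has
no voids a 1σ chromatin bead could slip through, and (b) a 1σ-wide equatorial
slice holds enough beads (≈50 at reduced scale) for the Fourier analysis.
A sparser shell would make the slice spectrum unmeasurable at desk scale.

### Initial placement and crosslinks

Chains are grown as compact self-avoiding walks (step 0.97σ, minimum
separation 0.75σ, backtracking on dead ends) around seed points spread over
well-separated directions inside the inner ~60% of the shell radius. A final
energy-capped push removes residual overlaps (to ≥ ~0.85σ) while keeping
backbone bonds well below their extensibility limit. Optional permanent
crosslinks join C–C bead pairs within 1.3σ (at most 2 extra bonds per bead)
using the backbone FENE spring.

## Dynamics

BAOAB-split Langevin integration at Δt = 0.005τ, unit mass, kT = 1, friction
γ = 1/τ; velocities start Maxwell–Boltzmann; total momentum is removed every
step so analyses live in the resting frame. Neighbor lists store pairs within
the per-type-pair cutoff plus a 0.5σ skin and rebuild when any bead moves half
the skin (cell-binned build, serial, deterministic for a fixed seed). Bond
overstretch, coincident beads and chromatin escape through the shell raise
errors naming the step.

The staged protocol is:

1. **shell relaxation** — chromatin–shell attractions off. The phase runs
   *overdamped* (friction ×10): the freshly built shell starts with every bond
   43% over rest, and an inertial collapse at γ = 1 overshoots into long-lived
   wrinkles; quasi-static contraction settles onto the rest geometry instead.
2. **polymer relaxation** — attractions on.
3. **production** — the analysis window; observables average the last half.

Full-scale step counts are 3×10⁴ / 10⁵ / 5×10⁶ (conventional production) and
10⁷ for inverted production. The reduced schedule divides the sampling phases
by 50 (production 10⁵ conventional / 2×10⁵ inverted) but keeps the shell
relaxation at 5×10³ steps: that phase is a physical-time transient whose
duration is set by friction and stiffness, not by system size, and 5×10³
overdamped steps are where the contraction has converged.

## Reduced scale

The desk-scale system preserves the dimensionless control parameters —
affinities in kT, volume fraction φ, heterochromatin fraction *f*, the chain
composition ratios — at R₀ = 14σ with 212-bead chains (35 C + 175 compartment
+ 2 T; the same 1:5 C:compartment ratio) and a 968-bead shell. Chain length is
set so that n_block = 8 chains fill the relaxed shell to φ ≈ 23%, matching the
full-scale condition labels φ = 14/19/23% for n_block = 4/6/8. (Keeping
one-tenth-length chains at R₀ = 14σ would drive φ to ~64% — jamming — so the
chain length, not the label, is what the reduction adjusts.) Mean E/F block
length scales with chain length (8 beads).

## Shape-fluctuation analysis

Per frame, shell beads within w/2 = 0.5σ of the equatorial plane through the
shell center are projected in-plane; their radial displacements from the
slice-mean radius are ordered by azimuth and linearly resampled onto a uniform
angular grid (next power of two ≥ 2× the bead count). The FFT amplitude is
normalized so an imposed cosine of amplitude A at mode q reports A at mode q;
modes 1..Q are kept (Q = 230 capped at the Nyquist bound of the grid) and
averaged over the last half of the frames. The RMS shape fluctuation is the
time-averaged standard deviation of the raw (non-resampled) displacements, so
Parseval's identity ties the two outputs together up to mode truncation
(asserted at 5%).

The shell center is estimated by an algebraic least-squares sphere fit, not
the bead center of mass: the COM of N surface beads carries an O(R/√N)
sampling error that leaks directly into the q = 1 mode (≈0.3σ at desk scale),
while the sphere fit is exact for an ideal sphere and robust for wrinkled
shells. Scenario summaries average the three orthogonal equatorial slices
(the model is isotropic); the single z-slice is the default for the low-level
API. Amplitudes and RMS are reported in raw σ by default, with an explicit
radius-normalized mode for cross-scale comparison.

Radial density profiles bin bead radii in units of the instantaneous mean
shell radius over [0, 1.1] and normalize by shell-volume, so each type's
profile integrates back to its bead count. Contact maps count bead pairs
within a cutoff (default 1.5σ) into genomic bins, with self-contacts on the
diagonal. Chain compaction reports per-chain gyration radii and pairwise
center-of-mass distances.

## Synthetic fixtures

`AnalyticShellFixture` places beads quasi-uniformly (randomly rotated
Fibonacci lattice — emulating the relaxed shell's even coverage) on a sphere
with imposed equatorial Fourier modes and optional radial noise. It exercises
the entire analysis stage without dynamics and makes the spectrum oracles
exact to ~1%. What it does not emulate: correlated frame-to-frame dynamics,
bead-density fluctuations of an interacting shell, and chromatin. Passing the
fixture tests validates the measurement pipeline, not the polymer physics.

## Scenario sweeps and statistics

`condition_grid()` enumerates the model's standard condition grid (74 scenarios): the
volume-fraction × internal-structure grid (φ ∈ {14, 19, 23}% × crosslinks ±
× C–C attraction ± × conventional/inverted), the heterochromatin–shell
affinity sweep (u_HS ∈ {0.375, 0.75, 1.5, 3} kT × scope both/C-only/F-only at
φ = 19%), the self-affinity grid (u_HH ∈ {0, 0.65, 1.30, default} × the four
u_HS values), the content sweep (f ∈ {10, 30, 45, 55, 75}% across the three
φ analogs plus the inverted series at φ = 19%), the f = 75% condition without
facultative self-affinity at φ = 14%, and the stiff-shell variant.

Directional claims (φ↑ ⇒ RMS↓, u_HS↑ ⇒ RMS↑, f = 75% > f = 10%,
conventional > inverted, crosslinks ≈ no change) are asserted on the rank
order of means over 3 seeds, not on effect magnitudes, which are
scale-dependent. Shape modes decorrelate slowly (hundreds of τ), so
seed-to-seed scatter — not within-run frame noise — dominates the
uncertainty; summaries therefore report mean ± sd over seeds. The acceptance
sweeps in the test suite use production runs of 3×10⁴ steps (150τ) per seed,
which is past the adsorption transient that establishes the radial
organization; the conventional-versus-inverted comparison uses the full
reduced production lengths.

## Numerical choices and degenerate inputs

- Pair singularities (r = 0) and bond overstretch abort the run with the
  offending indices rather than propagating NaN.
- A slice with fewer than 16 shell beads raises a sparse-slice error; Q above
  the grid Nyquist raises immediately.
- Fraction targets are met exactly in bead counts (round(f·n)); conversions
  prefer block boundaries when building (keeping blocks contiguous) and are
  uniform-random when reassigning an existing plan.
- Empty chain lists, zero-step phases and chromatin-free shells are all valid
  inputs (used by the shrinkage measurement and the controls).
- All randomness flows through seeded `numpy.random.Generator` instances;
  identical seeds reproduce trajectories bit-for-bit.

## Known limitations

- Full-scale runs (≈57k beads, 10⁷ steps) are out of desk reach; the package
  builds such systems but the dynamics loop is tuned for the reduced scale.
- The shell has no explicit bending rigidity; all elasticity comes from the
  bond network, so very soft (low-k) shells crumple thermally.
- No hydrodynamics, electrostatics, or active (nonequilibrium) processes —
  the model is quasi-equilibrium by construction.
- Quantitative fluctuation amplitudes at reduced scale are not the full-scale
  amplitudes; only dimensionless orderings and ratios are expected to carry
  over.
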