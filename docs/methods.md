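# Methods

`nanoduplex` models the electrophoretic translocation of nucleic-acid
duplexes through glass nanopores, contrasting the A-form-like RNA:DNA
hybrid (RD) with canonical B-form DNA:DNA (DD).  The package covers the
full chain from closed-form theory to event decoding; this note records
the models, their assumptions, the numerical choices, and what the
synthetic tests do and do not establish.

## Duplex parameterization

Each form is a `DuplexSpec`.  Two rises are stored and never silently
interchanged:

| parameter | DD (B-form) | RD (A-form-like) | role |
|---|---|---|---|
| theoretical rise | 0.34 nm | 0.26 nm | closed-form estimates |
| model rise | 0.34 nm | 0.277 nm | bead-chain construction |
| pitch | 10.44 bp (35.5 Å) | 11.6 bp (32.1 Å) | bookkeeping only |
| radius | 1.0 nm | 1.15 nm | SEM exclusion, friction |
| persistence length | 50 nm | 60 nm | bending constants |
| stretch modulus | 1000 pN | 560 pN | bond constants |
| charge | 2 e/bp | 2 e/bp | driving force |
| effective force / length | 20.98 pN/nm | 19.47 pN/nm | fixed input from all-atom work |
| hydrostatic mobility scale | 1.0 | 1.0 (configurable) | bead diffusivity |

The mobility ratio of the two forms is not available as a printed
number; it defaults to 1 and is exposed in `DuplexSpec.mobility_scale`.

Internal units are pN, nm, ns, elementary charge, mV, K; kT is computed
from the temperature (4.017 pN nm at the default 291 K).

## Theory module

Two zeroth-order pictures of the driving force are implemented.  The
line-charge estimate (force ∝ charge per unit length = 2e/rise) gives a
force ratio RD:DD of rise_DD/rise_RD ≈ 1.3 — an overestimate.  The
drag-balance estimate treats each duplex as a rigid rod with slender-body
friction γ = 2πηL/ln(L/r) moving at v = L/τ; with measured contour
lengths and dwell times the ratio is close to 1, i.e. equal force per
unit contour length.  The logarithm's O(1) end-correction constant is
omitted deliberately: only ratios of γ enter, and the prefactor
cancels.  Headline numbers are rounded half-up only at reporting time.

## Pore fields

The original workflow exported a finite-element (Poisson–Nernst–Planck
plus creeping flow) solution.  Here the central modeling simplification
is a **uniform-conductivity Laplace solve**: insulating walls (zero
normal gradient), Dirichlet electrodes at the chamber ends (0 mV cis,
+600 mV trans), axisymmetric (r, z) lattice at 10 Å axial × 5 Å lateral
spacing, node-centered, 0-based.  Electroosmotic screening is not
solved; it is represented by the empirical 1/32 reduction applied when
converting bare-charge potential gradients to effective forces.  Wall
surface charge (−0.01 C/m²) is carried as metadata only.  The error of
this simplification relative to the coupled solve cannot be quantified
from printed information; all conclusions drawn from the fields are
directional (ratios across duplex forms under the same field).

The solver is Gauss–Seidel SOR in a fixed sweep order (deterministic
regardless of threading), tolerance 1e−6 of the applied voltage per
sweep, cap 1e5 sweeps.  The on-axis singular term uses the standard
4(φ₁−φ₀)/dr² limit.  A pure single-angle cone solved this way matches
the analytic cone + access-resistance formula within a few percent (the
acceptance bound is 10%).

Wall voxels get a steric penalty u = k·d² (k = 4 kcal mol⁻¹ Å⁻²,
d = anisotropic Euclidean distance in Å to the nearest solution voxel,
computed in the (r, z) plane).  Invalid electrostatic voxels are filled
by iterative neighbor averaging (each pass assigns the mean of already
valid/filled 4-neighbors); the operation is idempotent and leaves valid
voxels untouched.  Chain segments outside the lattice feel zero force —
justified because the chambers extend beyond the solved region.

Pore shapes: conical pipette (5 nm aperture, 4.87° taper for 50 nm then
1.2°, 300 nm length, 300 × 150 nm chambers), cylinder and hourglass
membranes (narrowest section at z = 0), and a 3-D slit solved on a
Cartesian lattice with the same boundary rules.  Slit dimensions are
not known from printed information and must be supplied explicitly.

## Coarse-grained chains and Brownian dynamics

A duplex of n bp is a linear bead chain at `bp_per_bead` resolution
with constants mapped to conserve contour length, stretch modulus
(k_s = elastic/l₀), persistence length (discrete worm-like chain,
bending energy k_b(1−cos θ), k_b = Lp·kT/l₀), line charge (2 e/bp,
negative), and friction per length (free-draining; per-bead friction =
γ(L)/L × l₀ from the slender-body rod formula, giving D ≈ 2.5 nm²/ns
for a 1.7 nm DD segment).  The production resolution of the original
study (1 bp / 2 beads, ≥300 µs trajectories) is expressible but far
beyond desk scale; the desk defaults are 5 bp/bead and 0.2–0.9 kbp
chains.  The helical two-strand detail is collapsed onto the linear
chain (no torsional potential; the linking number is assumed relaxed).
Excluded volume is a short-range harmonic repulsion (diameter 2 nm,
50 pN/nm) between beads ≥3 apart, with a KD-tree neighbor list.

The integrator is Euler–Maruyama:
x ← x + (D/kT)F dt + √(2D dt) ξ.  Noise comes from a counter-based
Philox stream keyed by (seed, replicate) and consumed in fixed
(step, bead, coordinate) order, making runs bit-reproducible
independent of chunking.  The default `timestep_fs` is the production
value (40 fs); desk-scale runs use 1–2 ps, which keeps the stiffest
spring's stability parameter k_s·(D/kT)·dt below ~0.6 (stable; bond
variance inflated by <20%, with negligible effect on tangent
statistics and dwell times — verified by the bond-Boltzmann KS test at
small dt).  A per-bead force cap (500 pN) guards against the steep
steric wall; it only engages during wall contacts.

**RD force scaling.**  The per-bead electrophoretic scale is
(1/32) × (19.47/20.98) × (rise_RD/rise_DD) ≈ 0.756/32, chosen so the
*force per unit contour length* ratio RD:DD equals the all-atom
19.47/20.98 (the "8% higher force per unit length on DD").  Applying
the bare 19.47/20.98 per bead would, with RD beads at the shorter
2.77 Å spacing, make the RD force per length *larger* than DD's —
contradicting the all-atom result the scaling is meant to encode.

**Threading protocol.**  The chain starts as an exact equilibrium
worm-like-chain coil in the cis chamber with its leading bead on the
axis 25 nm outside the aperture.  A stiff restraint
(1 kcal mol⁻¹ Å⁻² = 695 pN/nm) on the leading bead moves to 12.5 nm
inside the pore at 0.5 nm/ns with only the steric potential active,
then settles briefly.  Production applies both lattices until every
bead passes the aperture plane (z = 0).  Replicates that are not
captured within the step budget (the released chain can retract — a
real feature of the stochastic capture process at these short chain
lengths) are flagged incomplete and treated as right-censored (+∞) in
median statistics; medians are reported only when more than half the
replicates completed.

## Persistence-length estimator

⟨t(s)·t(s+Δs)⟩ decays exactly geometrically for the discrete chain, so
every separation estimates the same slope, but the sampling variance
grows roughly as Δs³ while snapshots from one run decorrelate slowly at
large separation (the rotational relaxation of a 50 nm segment is tens
of µs).  The fit therefore uses weighted least squares on ln C over the
short-separation window (C ≳ 0.5) with *empirical* inverse-variance
weights computed across snapshots; this is dominated by the
single-joint statistics, for which a 600-bead chain provides hundreds
of effectively independent samples per snapshot.  The known estimator
biases (discretization: −l₀/ln⟨cos θ⟩ ≈ Lp − l₀/2·…, integrator
variance inflation at 1 ps) total a few percent, well inside the 15%
acceptance band.  Warm starts are exact discrete-WLC equilibrium
samples, so burn-in only relaxes bond lengths and the estimate is
unbiased at modest run lengths.  A bootstrap over snapshots provides
the standard error.

## Steric-exclusion-model currents

The pore is cut into 1 nm axial slabs.  Open pore: series sum of
Δz/(σA(z)) plus one access term 1/(4σr) per entrance, σ = 151 mS/cm
(4 M LiCl).  With a chain present, each slab loses a *deficit area* per
chain-segment crossing: π·r_ex² for a hard exclusion radius plus an
annulus correction for a linear conductivity ramp back to bulk
(defaults: r_ex = duplex radius, ramp length 1 nm).  The radial
conductivity-recovery profile near a duplex is not known in closed
form; it is a declared two-parameter stand-in, and only directions and
inequalities (wider duplex blocks more; blockade monotone in r_ex;
blockade ≤ open-pore current) are treated as robust.  The empty-pore
case reproduces the open-pore current exactly because both calculators
share one slab decomposition.  SEM traces are reported unfiltered at
the trajectory frame rate; the recording filter is emulated only in the
synthetic-data generator.  The slab-series formulation itself is this
package's own definition of the model.

## Event analysis

Pipeline: robust baseline → threshold detection (80 pA, 0.1 ms
minimum) → ECD filter (10–500 fC) → fold exclusion → 5-slot ID
decoding against the codebook {11100: RD, 11001: DD}, accepting either
read direction; patterns matching neither entry are recorded as
unclassified, never guessed.

Design choices that the experimental description leaves open, all
exposed in `EventFilterConfig`:

* **Baseline**: median of samples above the 40th percentile, with the
  Gaussian truncation bias (0.5244 σ, σ estimated from the truncated
  sample's 50th–90th percentile spread) removed.  Insensitive to event
  occupancies below ~20%.
* **Fold criterion**: an event is folded iff >15% of its non-spike
  samples are deeper than 1.8× its single-level median blockade.
  Label spikes are shielded by a dilated mask; deep segments wider
  than 50 samples (50 µs at 1 MHz) are treated as folds, not spikes.
* **Spikes**: ≥80 pA below the event level, width 3–50 samples.
* **Slot mapping** assumes constant velocity within an event (labels
  equally spaced along the molecule map linearly to time) — an
  approximation adequate for rectangular synthetic events.

Population statistics are means ± SEM with first-order error
propagation for ratios; no significance machinery beyond that.

## Synthetic data

The generator emulates the measured recordings: 1 MHz sampling,
Gaussian noise (30 pA), 4-pole Bessel 100 kHz zero-phase low-pass,
renewal-process arrivals (Poisson at low occupancy; >30% occupancy is
refused), rectangular events with label spikes at slot centers, and
folded contaminants (a fold at fraction f ∈ [0.20, 0.32] doubles the
depth over the folded section and shortens the event, conserving ECD).
The headline two-population experiment plants 80 linear events per
form with dwell medians 0.32 ms (RD) and 0.57 ms (DD) and blockade
depths 285/250 pA (ratio 1.14).  Dwell times are log-normal with 10%
geometric CV and depths have 10% CV — the experiments report only SEMs
of means, so these spreads are declared synthetic parameters chosen to
make recovery tests meaningful (the published scatter plots show
comparable dispersion).  Ground-truth tables are exact: an ideal
detector on a noise-free, unfiltered trace reproduces them
sample-for-sample.

What a green synthetic round trip establishes: the detector, filters,
decoder and statistics recover what was planted, at realistic noise.
What it does not establish: agreement with any real recording —
absolute blockade magnitudes are profile-dependent and event shapes are
idealized rectangles.

## Desk-scale acceptance configuration

* Persistence recovery: 600-bead chains, 5 seeds, 20 snapshots each
  (burn-in 5 ns, stride 2 ns, dt 1 ps).
* Translocation phenomenology: 450 bp bp-matched pair and a 367 bp
  DD contour-matched partner (367 × 0.34 = 450 × 0.277 = 124.8 nm),
  8 replicates per arm; geometry-robustness comparison at 360 bp,
  5 replicates per arm, across conical / cylindrical / hourglass
  lattices (coarsened to 20 Å × 10 Å with reduced chambers for test
  runtime).  These sizes sit inside the 0.2–0.9 kbp desk band; the
  full-length production configuration remains expressible but needs
  GPU-scale resources.

## Known limitations

* No hydrodynamic interactions between beads (free-draining), no
  torsional dynamics, no ion-concentration or fluid-velocity fields,
  no double-layer structure at charged walls.
* The Laplace + 1/32 stand-in cannot reproduce absolute currents or
  forces of the coupled PNP/flow solution; only form-to-form ratios
  are meaningful.
* Absolute experimental dwell times and blockade ratios (0.32/0.57 ms,
  1.14×) are not reachable from first principles at desk scale; they
  enter as synthetic-generator parameters, not as simulation outputs.
* Capture after release is stochastic for short desk-scale chains;
  median statistics are right-censored rather than conditioned on
  completion.
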