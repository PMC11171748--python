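# nanoduplex

Why does an RNA:DNA hybrid pass through a nanopore faster than a DNA:DNA
duplex with the same number of base pairs?  The hybrid adopts an
A-form-like helix — shorter rise per base pair (~0.26 nm vs 0.34 nm),
wider cross-section — so at equal base-pair count it is a shorter
molecule carrying the same total charge.  `nanoduplex` implements the
computational side of that question for researchers working on
solid-state nanopore sensing and molecular identification: closed-form
transport theory, a nanopipette field solver, coarse-grained Brownian
dynamics of duplex translocation, steric-exclusion-model (SEM) ionic
currents, and the event-analysis chain that decodes 5-bit molecular IDs
from labeled duplexes.

## The core models

**Force ratio.**  A line-charge picture predicts the driving force per
unit length F ∝ q·V/a (q = 2e per bp, a = rise), giving a force ratio

    F_RD / F_DD = a_DD / a_RD ≈ 0.34 / 0.26 ≈ 1.3,

which overestimates the hybrid's force.  Balancing the drive against
slender-body rod drag γ = 2πηL/ln(L/r) at velocity v = L/τ instead
gives

    F_RD / F_DD = [γ(L_RD)·L_RD/τ_RD] / [γ(L_DD)·L_DD/τ_DD] ≈ 1,

i.e. equal force per unit *contour length*: contour length, not charge
or base-pair count, sets the translocation velocity.

**Simulation chain.**  An axisymmetric Laplace solve (insulating walls,
600 mV across the chambers) stands in for the full coupled
PNP/creeping-flow problem; electroosmotic screening is absorbed into
the empirical 1/32 force reduction.  Duplexes are bead-spring chains
mapped to conserve contour, stretch modulus, persistence length (50 nm
DD / 60 nm RD), and line charge; an overdamped integrator with
counter-based noise threads them through the pore with a moving
restraint and releases them.  SEM converts trajectory frames to
currents by series slab conductances with a conductivity-exclusion zone
around the duplex.  The event module detects blockades (80 pA / 0.1 ms
thresholds), filters by event charge deficit (10–500 fC), rejects
folded molecules, and reads label spikes in five equal time slots
against the codebook `11100 → RD`, `11001 → DD`.

## Worked example

```python
from nanoduplex import theory as th

rd, dd = th.a_like(), th.b_form()
print(th.contour_length(3569, rd.theory_rise_nm))            # 927.94
print(th.force_ratio_line_charge(rd.theory_rise_nm,
                                 dd.theory_rise_nm))         # 1.3077
print(th.force_ratio_hydrodynamic(906.5, 0.32, 1144.4, 0.57))  # 1.1559
```

A 3569 bp hybrid is ~930 nm long; the naive line-charge force ratio is
~1.31; the drag-balance ratio evaluated with AFM-measured contours and
measured dwell times is ~1.16, close to one — the contour-length
picture.  The synthetic round trip (`python analysis/06_id_decoding.py`)
prints

```
planted events: 160; decoded linear events: 160
dwell-time ratio DD:RD = 1.765 +/- 0.026 (configured 0.57/0.32 = 1.781)
blockade ratio RD:DD   = 1.111 +/- 0.018 (configured 1.14)
```

showing the detector/decoder chain recovers the planted population
parameters within error.

There is also a thin CLI (`nanoduplex theory|fields|simulate|current|
analyze|synth`) over the same library functions.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the persistence lengths of free
coarse-grained chains for both duplex parameter sets (600-bead chains
at 5 bp/bead, five replicate seeds, field-free Brownian dynamics, then
an exponential fit of the tangent–tangent correlation) and writes one
JSON entry per target in nm.
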