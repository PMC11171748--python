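#!/usr/bin/env python
"""Build the nanopipette potential/steric lattices and verify them.

Solves the axisymmetric Laplace problem for the default conical
nanopipette at 600 mV, cross-checks the implied open-pore resistance
against the analytic cone + access formula, and writes the lattice to
results/fields/conical.h5 for reuse by the translocation driver.
"""

from pathlib import Path

from nanoduplex.fields import (conical_resistance_analytic, solve_potential,
                               solved_resistance)
from nanoduplex.pore import build_pore
from nanoduplex.sem import open_pore_current

ROOT = Path(__file__).resolve().parents[1]
SIGMA = 15.1  # 151 mS/cm


def main() -> None:
    geo = build_pore("conical_pipette")
    print("solving conical pipette at 600 mV (10 A x 5 A lattice)...")
    grid = solve_potential(geo, 600.0)
    out = ROOT / "results" / "fields"
    out.mkdir(parents=True, exist_ok=True)
    grid.save_h5(out / "conical.h5")

    R_field = solved_resistance(grid, SIGMA)
    cone = build_pore("conical_pipette", taper_near_extent_nm=1000.0,
                      chamber_length_nm=100, chamber_radius_nm=100)
    R_solved = solved_resistance(solve_potential(cone, 600.0, dz_A=20,
                                                 dr_A=10), SIGMA)
    R_ref = conical_resistance_analytic(cone, SIGMA)

    print(f"pipette open-pore current (SEM slabs): "
          f"{open_pore_current(geo, 600.0, 151.0):,.0f} pA")
    print(f"pipette resistance from solved field:  {R_field:.4f} 1/nS")
    print(f"single-cone solver vs analytic oracle: "
          f"{R_solved:.4f} vs {R_ref:.4f} 1/nS "
          f"({100 * (R_solved / R_ref - 1):+.1f}%)")
    print(f"lattice written to {out / 'conical.h5'}")


if __name__ == "__main__":
    main()
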