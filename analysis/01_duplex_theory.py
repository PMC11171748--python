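#!/usr/bin/env python
"""Closed-form comparison of the two duplex forms.

Evaluates the contour-length arithmetic, the naive line-charge force
ratio, the drag-balance force ratio from measured lengths and dwell
times, and the cylinder surface charge for the A-form-like RNA:DNA
hybrid (RD) versus B-form DNA:DNA (DD).  Writes
results/theory_summary.csv.
"""

from pathlib import Path

import pandas as pd

from nanoduplex import theory as th

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rd, dd = th.a_like(), th.b_form()
    rows = []

    L_rd = th.contour_length(3569, rd.theory_rise_nm)
    L_dd = th.contour_length(3621, dd.theory_rise_nm)
    rows += [
        ("contour_rd_3569bp_nm", L_rd,
         "3.6 kb hybrid at the 0.26 nm A-form rise (~930 nm)"),
        ("contour_dd_3621bp_nm", L_dd,
         "3.6 kb DNA:DNA at the 0.34 nm B-form rise"),
        ("shortening_pct", 100 * (1 - rd.theory_rise_nm / dd.theory_rise_nm),
         "A-vs-B contour shortening at equal bp count (~24%)"),
        ("rise_from_afm_rd_A", th.rise_from_length(906.5, 3569),
         "rise implied by the AFM contour of the hybrid"),
        ("rise_from_afm_dd_A", th.rise_from_length(1144.4, 3621),
         "rise implied by the AFM contour of DNA:DNA"),
        ("force_ratio_line_charge",
         th.force_ratio_line_charge(rd.theory_rise_nm, dd.theory_rise_nm),
         "naive charge-per-length estimate (overestimates, ~1.3)"),
        ("force_ratio_drag_balance_bp_matched",
         th.force_ratio_hydrodynamic(906.5, 0.32, 1144.4, 0.57),
         "rod-drag balance with AFM lengths and measured dwell times"),
        ("force_ratio_drag_balance_contour_matched",
         th.force_ratio_hydrodynamic(930, 0.36, 930, 0.35),
         "contour-matched pair: close to one"),
        ("sigma_rd_e_nm2", th.cylinder_surface_charge(
            rd.charge_per_bp, rd.radius_nm, rd.theory_rise_nm),
         "cylinder surface charge of the hybrid"),
        ("sigma_dd_e_nm2", th.cylinder_surface_charge(
            dd.charge_per_bp, dd.radius_nm, dd.theory_rise_nm),
         "cylinder surface charge of DNA:DNA"),
        ("force_per_length_excess_pct",
         100 * (dd.force_per_length_pN_nm / rd.force_per_length_pN_nm - 1),
         "all-atom effective force per unit length, DD over RD (~8%)"),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value", "note"])
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "theory_summary.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:0.3f}"))
    print("\nThe line-charge picture predicts a ~1.3x larger force on the "
          "hybrid;\nthe drag-balance picture using measured lengths and "
          "times gives ~1,\nidentifying contour length as the controlling "
          "variable.")


if __name__ == "__main__":
    main()
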