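#!/usr/bin/env python
"""Synthetic two-population experiment through the event pipeline.

Generates the headline synthetic measurement (80 linear events per
duplex, dwell medians 0.32/0.57 ms, blockade ratio 1.14, 5-bit label
IDs), runs detection / ECD filtering / fold exclusion / ID decoding,
and reports the recovered population statistics.  Writes
results/reference_events.tsv and results/reference_summary.csv.
"""

from pathlib import Path

from nanoduplex.events import analyze_trace, ratio_with_error, summarize
from nanoduplex.synth import gen_reference_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 12


def main() -> None:
    trace, truth = gen_reference_experiment(SEED)
    table = analyze_trace(trace)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "reference_events.tsv", sep="\t", index=False)
    s = summarize(table[table.identity.isin(["RD", "DD"])])
    s.to_csv(OUT / "reference_summary.csv")
    print(s.round(4).to_string())

    r_tau, e_tau = ratio_with_error(
        s.loc["DD", "tau_mean_ms"], s.loc["DD", "tau_sem_ms"],
        s.loc["RD", "tau_mean_ms"], s.loc["RD", "tau_sem_ms"])
    r_di, e_di = ratio_with_error(
        s.loc["RD", "dI_mean_pA"], s.loc["RD", "dI_sem_pA"],
        s.loc["DD", "dI_mean_pA"], s.loc["DD", "dI_sem_pA"])
    print(f"\nplanted events: {len(truth)}; decoded linear events: "
          f"{int(s.n.sum())}")
    print(f"dwell-time ratio DD:RD = {r_tau:.3f} +/- {e_tau:.3f} "
          f"(configured 0.57/0.32 = 1.781)")
    print(f"blockade ratio RD:DD   = {r_di:.3f} +/- {e_di:.3f} "
          f"(configured 1.14)")


if __name__ == "__main__":
    main()
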