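"""Ground-truthed synthetic inputs for every pipeline stage.

Generates ionic-current recordings that emulate the measured data:
a Gaussian-noise baseline sampled at 1 MHz, Poisson-arriving
translocation events from two duplex populations with distinct dwell
times and blockade depths, downward label spikes encoding the 5-bit
molecular IDs ("11100" for the hybrid, "11001" for DNA:DNA), folded
contaminants, and a 4-pole Bessel 100 kHz low-pass emulating the
amplifier.  Every generator is a pure function of (spec, seed) and
returns an exact ground-truth table alongside the trace.

Event shape is rectangular plus spikes — the minimal shape consistent
with the published example events; dwell times are log-normal with a
10% geometric CV (the experiments report only the SEM of the mean, so
the spread is a declared synthetic parameter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .chain import ChainState, build_chain, wlc_positions
from .sem import CurrentTrace
from .theory import DuplexSpec


@dataclass(frozen=True)
class PopulationSpec:
    """One event population: ID code, dwell-time law, depths, counts."""

    id_code: str = "11100"
    tau_median_ms: float = 0.32
    tau_gcv: float = 0.10          # geometric coefficient of variation
    depth_pA: float = 285.0
    depth_cv: float = 0.10         # event-to-event blockade spread
    spike_depth_pA: float = 150.0
    n_events: Optional[int] = 80
    rate_Hz: Optional[float] = None
    fold_fraction: float = 0.0
    spike_width_samples: int = 8

    def __post_init__(self) -> None:
        if self.depth_pA <= 0 or self.spike_depth_pA < 0:
            raise ValueError("depths must be positive")
        if self.n_events is None and self.rate_Hz is None:
            raise ValueError("give n_events or rate_Hz")


@dataclass(frozen=True)
class TraceSpec:
    duration_s: float = 1.2
    baseline_pA: float = 8600.0
    noise_sd_pA: float = 30.0
    sampling_rate_Hz: float = 1e6
    lowpass_kHz: Optional[float] = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s * self.sampling_rate_Hz > 2e8:
            raise ValueError("trace would not fit the memory budget")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def label_positions(n_bp: int, code: str) -> np.ndarray:
    """Base-pair indices of the bound labels: slot centers
    (i + 1/2) * n_bp / len(code) for every set bit."""
    if not code:
        raise ValueError("empty code")
    n_slots = len(code)
    idx = [(i + 0.5) * n_bp / n_slots for i, b in enumerate(code) if b == "1"]
    return np.array(idx)


def _draw_tau_ms(pop: PopulationSpec, rng: np.random.Generator) -> float:
    mu = np.log(pop.tau_median_ms)
    sigma = np.sqrt(np.log(1.0 + pop.tau_gcv ** 2))
    return float(np.exp(rng.normal(mu, sigma)))


def gen_trace(spec: TraceSpec, populations: Sequence[PopulationSpec]
              ) -> Tuple[CurrentTrace, pd.DataFrame]:
    """Synthesize a trace with planted events and its exact truth table.

    Events from all populations are interleaved by a renewal process
    with exponential gaps (Poisson arrivals at low occupancy); total
    expected occupancy above 30% is refused.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_samples = int(spec.duration_s * spec.sampling_rate_Hz)
    rate = spec.sampling_rate_Hz

    # build per-population event queues
    jobs = []
    for p_idx, pop in enumerate(populations):
        n = pop.n_events
        if n is None:
            n = rng.poisson(pop.rate_Hz * spec.duration_s)
        for _ in range(n):
            jobs.append((p_idx, _draw_tau_ms(pop, rng)))
    total_busy_s = sum(tau for _, tau in jobs) * 1e-3
    if jobs and total_busy_s > 0.3 * spec.duration_s:
        raise ValueError(
            f"expected occupancy {total_busy_s / spec.duration_s:.0%} "
            "exceeds the 30% feasibility bound")
    order = rng.permutation(len(jobs))

    x = np.full(n_samples, spec.baseline_pA)
    truth_rows = []
    # 0.8 keeps the expected end of the last event inside the trace so
    # the planted count is (almost surely) the realized count
    mean_gap_s = (0.8 * (spec.duration_s - total_busy_s) / (len(jobs) + 1)
                  if jobs else spec.duration_s)
    cursor = 0
    for j in order:
        p_idx, tau_ms = jobs[j]
        pop = populations[p_idx]
        gap = rng.exponential(mean_gap_s)
        start = cursor + max(int(gap * rate), 1)
        n_ev = int(tau_ms * 1e-3 * rate)
        if n_ev < 2 or start + n_ev >= n_samples:
            continue
        folded = rng.random() < pop.fold_fraction
        depth = pop.depth_pA * max(1.0 + pop.depth_cv * rng.standard_normal(),
                                   0.2)
        if folded:
            # fold at fraction f from one end: the doubled-over section
            # translocates at 2x depth, total ECD is conserved while the
            # duration shrinks to (1-f) tau.  f < 1/3 keeps the
            # single-level median at the unfolded depth.
            f = rng.uniform(0.20, 0.32)
            n_fold = max(int(n_ev * (1.0 - f)), 4)
            n_deep = max(int(n_ev * f), 1)
            seg = np.full(n_fold, depth)
            seg[:n_deep] = 2 * depth
            n_ev = n_fold
        else:
            seg = np.full(n_ev, depth)
            w = pop.spike_width_samples
            for i, bit in enumerate(pop.id_code):
                if bit != "1":
                    continue
                c = int((i + 0.5) / len(pop.id_code) * n_ev)
                lo = max(c - w // 2, 0)
                seg[lo: min(lo + w, n_ev)] += pop.spike_depth_pA
        x[start: start + n_ev] -= seg
        truth_rows.append(dict(
            population=p_idx, id_code=pop.id_code,
            start_s=start / rate, end_s=(start + n_ev) / rate,
            tau_ms=n_ev / rate * 1e3, depth_pA=depth,
            folded=folded))
        cursor = start + n_ev

    x = x + rng.normal(0.0, spec.noise_sd_pA, n_samples)
    meta = {"filtered": False}
    if spec.lowpass_kHz:
        sos = signal.bessel(4, spec.lowpass_kHz * 1e3, btype="low",
                            fs=rate, output="sos", norm="mag")
        x = signal.sosfiltfilt(sos, x)
        meta = {"filtered": True, "lowpass_kHz": spec.lowpass_kHz,
                "family": "bessel4-zero-phase"}
    truth = pd.DataFrame(truth_rows)
    trace = CurrentTrace(samples_pA=x, sampling_rate_Hz=rate,
                         baseline_pA=spec.baseline_pA, filter_metadata=meta)
    return trace, truth


def reference_populations() -> List[PopulationSpec]:
    """The two-duplex measurement conditions: 80 linear events each,
    dwell medians 0.32 ms (hybrid, "11100") and 0.57 ms (DNA:DNA,
    "11001"), blockade-depth ratio 1.14 (hybrid deeper)."""
    return [
        PopulationSpec(id_code="11100", tau_median_ms=0.32,
                       depth_pA=285.0, n_events=80),
        PopulationSpec(id_code="11001", tau_median_ms=0.57,
                       depth_pA=250.0, n_events=80),
    ]


def gen_reference_experiment(seed: int) -> Tuple[CurrentTrace, pd.DataFrame]:
    """Two-population synthetic experiment matching the headline
    measurement (see :func:`reference_populations`)."""
    spec = TraceSpec(seed=seed)
    return gen_trace(spec, reference_populations())


def gen_free_chain(duplex: DuplexSpec, n_bp: int, bp_per_bead: int,
                   seed: int) -> ChainState:
    """Free-chain fixture: CG chain warm-started from the exact
    discrete worm-like-chain equilibrium ensemble."""
    state = build_chain(duplex, n_bp, bp_per_bead)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    state.positions_nm = wlc_positions(
        state.n_beads, float(state.rest_length_nm[0]),
        duplex.persistence_nm, rng)
    return state
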