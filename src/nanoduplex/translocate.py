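"""Threading and field-driven translocation protocols.

A run has three phases:

1. placement — an equilibrium worm-like-chain coil is generated in the
   cis chamber with its leading bead at the restraint start point;
2. threading — a stiff harmonic restraint (1 kcal/mol/A^2) on the
   leading bead is moved from 25 nm outside to 12.5 nm inside the
   aperture while only the steric pore potential acts;
3. production — the restraint is released and both the electrostatic
   and steric lattices act until every bead has passed the aperture
   plane (z = 0) or the step budget is exhausted.

Incomplete runs are flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .bd import BDConfig, ChunkRunner
from .chain import ChainState, wlc_positions
from .fields import PotentialGrid


class ThreadingError(RuntimeError):
    def __init__(self, msg, state=None):
        super().__init__(msg)
        self.state = state


@dataclass
class Trajectory:
    """Recorded frames of one run."""

    frames: np.ndarray          # (F, N, 3)
    times_us: np.ndarray        # (F,)
    replicate: int = 0

    def __post_init__(self) -> None:
        if len(self.times_us) > 1 and np.any(np.diff(self.times_us) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def save_h5(self, path, config_hash: str = "") -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames)
            f.create_dataset("times_us", data=self.times_us)
            f.attrs["replicate"] = self.replicate
            f.attrs["config_hash"] = config_hash

    def save_xyz(self, path) -> None:
        with open(path, "w") as f:
            for frame, t in zip(self.frames, self.times_us):
                f.write(f"{len(frame)}\nt_us={t:.6f}\n")
                for x, y, z in frame:
                    f.write(f"C {x:.3f} {y:.3f} {z:.3f}\n")


@dataclass
class TranslocationResult:
    translocation_time_us: Optional[float]
    completed: bool
    replicate: int
    trajectory: Optional[Trajectory] = None

    def __post_init__(self) -> None:
        if self.completed and self.translocation_time_us is None:
            raise ValueError("completed run must carry a time")


def place_chain_cis(state: ChainState, config: BDConfig,
                    replicate: int = 0, max_tries: int = 50,
                    geometry=None) -> ChainState:
    """Coil the chain in the cis chamber, leading bead at the restraint
    start point on the axis, growing away from the aperture (-z)."""
    from .bd import noise_stream
    rng = noise_stream(config.seed, replicate + 700_000)
    start = np.array([0.0, 0.0, config.restraint_start_z_nm])
    lp = state.duplex.persistence_nm
    l0 = float(state.rest_length_nm[0])
    if geometry is not None:
        z_cap = geometry.pore_z_range_nm[0] - 1.0
        r_cap = geometry.chamber_radius_nm - 5.0
    else:
        z_cap, r_cap = -0.5, 140.0
    pos = None
    for _ in range(max_tries):
        cand = wlc_positions(state.n_beads, l0, lp, rng, start=start,
                             direction=(0.0, 0.0, -1.0))
        if cand[:, 2].max() < z_cap and np.hypot(
                cand[:, 0], cand[:, 1]).max() < r_cap:
            pos = cand
            break
    if pos is None:  # fall back: clamp into the chamber
        pos = cand
        pos[:, 2] = np.minimum(pos[:, 2], z_cap)
    out = state.copy()
    out.positions_nm = pos
    return out


def thread_chain(state: ChainState, grid: PotentialGrid, config: BDConfig,
                 replicate: int = 0) -> ChainState:
    """Run the moving-restraint threading protocol (steric only)."""
    if config.seed is None:
        raise ValueError("threading requires a seed")
    runner = ChunkRunner(state, config, grid=grid, use_field=False,
                         use_steric=True, replicate=replicate)
    dist = abs(config.restraint_end_z_nm - config.restraint_start_z_nm)
    n_steps = max(int(dist / (config.thread_speed_nm_ns * config.dt_ns)), 1)
    runner.run(n_steps, restraint=(0, config.restraint_constant_pN_nm,
                                   config.restraint_start_z_nm,
                                   config.restraint_end_z_nm))
    if config.settle_steps:
        runner.run(config.settle_steps,
                   restraint=(0, config.restraint_constant_pN_nm,
                              config.restraint_end_z_nm,
                              config.restraint_end_z_nm))
    out = state.copy()
    out.positions_nm = runner.snapshot()
    lead_z = out.positions_nm[0, 2]
    sigma = np.sqrt(config.kT / config.restraint_constant_pN_nm)
    if abs(lead_z - config.restraint_end_z_nm) > max(3 * sigma, 1.0):
        raise ThreadingError(
            f"threading failed: leading bead at z={lead_z:.2f} nm "
            f"(target {config.restraint_end_z_nm} nm)", state=out)
    return out


def run_translocation(state: ChainState, grid: PotentialGrid,
                      config: BDConfig, replicates: int = 1,
                      record: bool = False) -> List[TranslocationResult]:
    """Thread and translocate ``replicates`` independent copies.

    Each replicate derives its own noise stream from (seed, replicate).
    Returns one result per replicate; runs that exhaust ``max_steps``
    are returned with ``completed=False``.
    """
    results: List[TranslocationResult] = []
    for rep in range(replicates):
        placed = place_chain_cis(state, config, replicate=rep,
                                 geometry=grid.geometry)
        threaded = thread_chain(placed, grid, config, replicate=rep)
        runner = ChunkRunner(threaded, config, grid=grid, use_field=True,
                             use_steric=True, replicate=rep + 10_000)
        frames = [runner.snapshot()] if record else []
        times = [0.0] if record else []
        done_step = -1
        steps = 0
        while steps < config.max_steps:
            block = min(config.record_stride, config.max_steps - steps)
            before = runner.steps_done
            res = runner.run(block, term_all_z=True)
            steps += (res - before) if res >= 0 else block
            if record:
                frames.append(runner.snapshot())
                times.append(steps * config.dt_ns * 1e-3)
            if res >= 0:
                done_step = steps
                break
        completed = done_step >= 0
        traj = None
        if record:
            traj = Trajectory(frames=np.array(frames),
                              times_us=np.array(times), replicate=rep)
        results.append(TranslocationResult(
            translocation_time_us=(done_step * config.dt_ns * 1e-3
                                   if completed else None),
            completed=completed, replicate=rep, trajectory=traj))
    return results


def censored_times_us(results: List[TranslocationResult],
                      config: BDConfig) -> np.ndarray:
    """Per-replicate dwell times with incomplete runs right-censored.

    An incomplete replicate (chain not captured within the step budget)
    is recorded as +inf; the sample median remains well defined as long
    as more than half of the replicates completed.
    """
    out = []
    for r in results:
        out.append(r.translocation_time_us if r.completed else np.inf)
    return np.asarray(out, float)


def median_translocation_time_us(results: List[TranslocationResult],
                                 config: Optional[BDConfig] = None,
                                 censor: bool = True) -> float:
    if censor and config is not None:
        med = float(np.median(censored_times_us(results, config)))
        if not np.isfinite(med):
            raise ValueError("fewer than half the replicates completed")
        return med
    times = [r.translocation_time_us for r in results if r.completed]
    if not times:
        raise ValueError("no completed replicates")
    return float(np.median(times))


def bootstrap_ratio_ci(times_num, times_den, n_boot: int = 2000,
                       seed: int = 0, level: float = 0.95):
    """Bootstrap CI for the ratio of medians of two replicate sets."""
    rng = np.random.default_rng(seed)
    a = np.asarray(times_num, float)
    b = np.asarray(times_den, float)
    ratios = np.empty(n_boot)
    with np.errstate(invalid="ignore"):
        for i in range(n_boot):
            ratios[i] = (np.median(rng.choice(a, a.size))
                         / np.median(rng.choice(b, b.size)))
    alpha = (1.0 - level) / 2
    return (float(np.nanquantile(ratios, alpha)),
            float(np.nanquantile(ratios, 1.0 - alpha)))
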