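"""Steric-exclusion-model (SEM) ionic currents.

The pore is decomposed into axial slabs.  Each slab conducts like a
disk of electrolyte whose conductivity is reduced where the duplex
excludes ions: conductivity is zero within ``exclusion_radius`` of the
duplex axis and recovers to bulk over ``recovery_length`` (step or
linear ramp).  Slab conductances combine in series together with one
access-resistance term, 1/(4 sigma r), per entrance.  An empty pore
reproduces the open-pore current exactly because both calculators share
the same slab decomposition.

The radial conductivity-recovery profile near a duplex is not known in
closed form; it is a two-parameter stand-in, and only directions and
inequalities (deeper blockade for the wider duplex, monotonicity in the
exclusion radius) are treated as robust conclusions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pore import PoreGeometry
from .units import MS_CM_TO_NS_NM


class ProfileShape(str, enum.Enum):
    STEP = "step"
    LINEAR_RAMP = "linear_ramp"


@dataclass(frozen=True)
class ConductivityProfile:
    """sigma(distance to duplex axis); bulk defaults to 4 M LiCl."""

    bulk_mS_cm: float = 151.0
    exclusion_radius_nm: float = 1.0
    recovery_length_nm: float = 1.0
    shape: ProfileShape = ProfileShape.LINEAR_RAMP

    def __post_init__(self) -> None:
        if self.bulk_mS_cm <= 0 or self.exclusion_radius_nm <= 0:
            raise ValueError("bulk conductivity and exclusion radius "
                             "must be positive")
        if self.recovery_length_nm < 0:
            raise ValueError("recovery length must be non-negative")

    @property
    def bulk_nS_nm(self) -> float:
        return self.bulk_mS_cm * MS_CM_TO_NS_NM

    def deficit_area_nm2(self) -> float:
        """Integral of (1 - sigma(d)/bulk) over the plane around one
        perpendicular duplex crossing."""
        r0 = self.exclusion_radius_nm
        core = np.pi * r0 ** 2
        if self.shape is ProfileShape.STEP or self.recovery_length_nm == 0:
            return core
        rho = self.recovery_length_nm
        # linear ramp: integral_{r0}^{r0+rho} (1 - (d - r0)/rho) 2 pi d dd
        return core + 2.0 * np.pi * (rho * r0 / 2.0 + rho ** 2 / 6.0)


@dataclass
class CurrentTrace:
    """Uniformly sampled ionic-current record."""

    samples_pA: np.ndarray
    sampling_rate_Hz: float = 1e6
    baseline_pA: Optional[float] = None
    filter_metadata: Optional[dict] = None

    def __post_init__(self) -> None:
        self.samples_pA = np.asarray(self.samples_pA, float)
        if self.sampling_rate_Hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples_pA)):
            raise ValueError("samples must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples_pA.size) / self.sampling_rate_Hz

    def save_h5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("samples_pA", data=self.samples_pA)
            f.attrs["sampling_rate_Hz"] = self.sampling_rate_Hz
            if self.baseline_pA is not None:
                f.attrs["baseline_pA"] = self.baseline_pA

    @classmethod
    def load_h5(cls, path) -> "CurrentTrace":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(samples_pA=f["samples_pA"][...],
                       sampling_rate_Hz=float(f.attrs["sampling_rate_Hz"]),
                       baseline_pA=(float(f.attrs["baseline_pA"])
                                    if "baseline_pA" in f.attrs else None))

    def save_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_s": self.times_s,
                      "current_pA": self.samples_pA}).to_csv(path, index=False)


# ---------------------------------------------------------------------------

def _slab_edges(geometry: PoreGeometry, dz_nm: float) -> np.ndarray:
    zlo, zhi = geometry.pore_z_range_nm
    n = max(int(round((zhi - zlo) / dz_nm)), 1)
    return np.linspace(zlo, zhi, n + 1)


def _series_resistance(geometry: PoreGeometry, sigma_nS_nm: float,
                       dz_nm: float, deficit_per_slab=None) -> float:
    edges = _slab_edges(geometry, dz_nm)
    zc = 0.5 * (edges[:-1] + edges[1:])
    dz = np.diff(edges)
    area = np.pi * np.asarray(geometry.wall_radius(zc)) ** 2
    if deficit_per_slab is not None:
        area = np.maximum(area - deficit_per_slab, 0.02 * area)
    if np.any(area <= 0):
        raise ValueError("zero-area slab in pore decomposition")
    R = float(np.sum(dz / (sigma_nS_nm * area)))
    zlo, zhi = geometry.pore_z_range_nm
    for z_end in (zlo, zhi):
        r_end = float(geometry.wall_radius(
            z_end + (1e-9 if z_end == zlo else -1e-9)))
        R += 1.0 / (4.0 * sigma_nS_nm * r_end)
    return R


def open_pore_current(geometry: PoreGeometry, voltage_mV: float = 600.0,
                      bulk_mS_cm: float = 151.0, dz_nm: float = 1.0) -> float:
    """Baseline current (pA): series slab resistances plus access terms."""
    sigma = bulk_mS_cm * MS_CM_TO_NS_NM
    return voltage_mV / _series_resistance(geometry, sigma, dz_nm)


def blockade_current(frame_nm: np.ndarray, geometry: PoreGeometry,
                     profile: ConductivityProfile,
                     voltage_mV: float = 600.0, dz_nm: float = 1.0) -> float:
    """Current (pA) with a bead chain occupying the pore.

    Each slab loses the profile's deficit area once per chain segment
    crossing it; the duplex axis is the polyline through the beads.
    """
    frame = np.asarray(frame_nm, float)
    if frame.ndim != 2 or not np.all(np.isfinite(frame)):
        raise ValueError("frame must be a finite (N, 3) array")
    edges = _slab_edges(geometry, dz_nm)
    deficit = np.zeros(edges.size - 1)
    dA = profile.deficit_area_nm2()
    z0, z1 = frame[:-1, 2], frame[1:, 2]
    lo = np.minimum(z0, z1)
    hi = np.maximum(z0, z1)
    # count segment crossings per slab midplane
    mid = 0.5 * (edges[:-1] + edges[1:])
    for m_idx, m in enumerate(mid):
        deficit[m_idx] = dA * np.count_nonzero((lo <= m) & (hi > m))
    sigma = profile.bulk_nS_nm
    R = _series_resistance(geometry, sigma, dz_nm, deficit_per_slab=deficit)
    return voltage_mV / R


def trace_from_trajectory(traj, geometry: PoreGeometry,
                          profile: ConductivityProfile,
                          voltage_mV: float = 600.0,
                          dz_nm: float = 1.0) -> CurrentTrace:
    """One SEM current sample per trajectory frame (unfiltered)."""
    frames = np.asarray(traj.frames, float)
    if frames.size == 0:
        raise ValueError("empty trajectory")
    samples = np.array([
        blockade_current(f, geometry, profile, voltage_mV, dz_nm)
        for f in frames])
    times = np.asarray(traj.times_us, float)
    if len(times) > 1:
        rate = 1.0 / ((times[1] - times[0]) * 1e-6)
    else:
        rate = 1.0
    return CurrentTrace(
        samples_pA=samples, sampling_rate_Hz=rate,
        baseline_pA=open_pore_current(geometry, voltage_mV,
                                      profile.bulk_mS_cm, dz_nm),
        filter_metadata={"filtered": False, "frame_based": True})


def average_traces(traces) -> CurrentTrace:
    """Average replicate traces over their common length."""
    n = min(t.samples_pA.size for t in traces)
    stack = np.vstack([t.samples_pA[:n] for t in traces])
    return CurrentTrace(samples_pA=stack.mean(axis=0),
                        sampling_rate_Hz=traces[0].sampling_rate_Hz,
                        baseline_pA=traces[0].baseline_pA)


def conical_current_analytic(geometry: PoreGeometry, voltage_mV: float,
                             bulk_mS_cm: float) -> float:
    """Closed-form cone + access oracle (pA), for solver cross-checks."""
    sigma = bulk_mS_cm * MS_CM_TO_NS_NM
    zlo, zhi = geometry.pore_z_range_nm
    r1 = float(geometry.wall_radius(zlo + 1e-9))
    r2 = float(geometry.wall_radius(zhi - 1e-9))
    R = (zhi - zlo) / (sigma * np.pi * r1 * r2)
    R += 1.0 / (4 * sigma * r1) + 1.0 / (4 * sigma * r2)
    return voltage_mV / R
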