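"""Overdamped Brownian-dynamics integrator.

Euler–Maruyama update per bead:

    x <- x + (D/kT) F dt + sqrt(2 D dt) xi,   xi ~ N(0, 1) per coordinate

Noise is drawn from a counter-based Philox stream keyed by
(seed, replicate) and consumed in fixed (step, bead, coordinate) order,
so a run is bit-reproducible regardless of chunking or thread count.

The hot path is a numba kernel that advances a chunk of steps with
pre-generated noise; :func:`bd_step` is the reference single-step
implementation used by tests and small studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numba import njit

from .chain import ChainState
from .units import kT as _kT


@dataclass
class BDConfig:
    """Integration and protocol parameters.

    ``timestep_fs`` defaults to the production value (40 fs); desk-scale
    studies typically raise it to 1000-2000 fs, still far below the
    stiffest spring's stability limit at 5 bp/bead.  ``seed`` is
    mandatory for any stochastic run.
    """

    timestep_fs: float = 40.0
    temperature_K: float = 291.0
    seed: Optional[int] = None
    record_stride: int = 2000
    max_steps: int = 10_000_000
    # threading protocol
    restraint_constant_pN_nm: float = 694.77   # 1 kcal/mol/A^2
    restraint_start_z_nm: float = -25.0
    restraint_end_z_nm: float = 12.5
    thread_speed_nm_ns: float = 0.5
    settle_steps: int = 5000
    # numerical guards
    force_cap_pN: float = 500.0
    # excluded volume (short-range harmonic repulsion, non-neighbor beads)
    excluded_volume: bool = True
    ev_sigma_nm: float = 2.0
    ev_k_pN_nm: float = 50.0
    ev_rebuild_steps: int = 400
    ev_skin_nm: float = 3.0

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")

    @property
    def dt_ns(self) -> float:
        return self.timestep_fs * 1e-6

    @property
    def kT(self) -> float:
        return _kT(self.temperature_K)


def noise_stream(seed: int, replicate: int = 0) -> np.random.Generator:
    """Philox generator keyed by (seed, replicate)."""
    if seed is None:
        raise ValueError("a seed is mandatory for stochastic runs")
    key = np.array([np.uint64(seed), np.uint64(replicate)], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def bd_step(state: ChainState, force_field: Callable[[np.ndarray], np.ndarray],
            dt_ns: float, rng: np.random.Generator,
            kT_pN_nm: float = 4.0177) -> ChainState:
    """Advance one step (reference implementation).

    ``force_field`` maps positions (N, 3) -> total forces (N, 3) in pN.
    """
    if dt_ns <= 0:
        raise ValueError("dt must be positive")
    F = np.asarray(force_field(state.positions_nm), float)
    if not np.all(np.isfinite(F)):
        bad = int(np.where(~np.isfinite(F).all(axis=1))[0][0])
        raise FloatingPointError(f"non-finite force on bead {bad}")
    D = state.diffusivity_nm2_ns[:, None]
    xi = rng.standard_normal(state.positions_nm.shape)
    new = (state.positions_nm + D / kT_pN_nm * F * dt_ns
           + np.sqrt(2.0 * D * dt_ns) * xi)
    if not np.all(np.isfinite(new)):
        bad = int(np.where(~np.isfinite(new).all(axis=1))[0][0])
        raise FloatingPointError(f"non-finite displacement on bead {bad}")
    out = state.copy()
    out.positions_nm = new
    return out


# ---------------------------------------------------------------------------
# fast chunked kernel

@njit(cache=True)
def _advance_chunk(pos, noise, dt, mob, sig,          # (N,3),(S,N,3),f,(N,),(N,)
                   l0, ks, kb,                        # bonds / joints
                   qpref,                             # (N,) pN per (mV/nm)
                   Ez, Er, Fsz, Fsr, z0, r0, idz, idr,
                   use_field, use_steric,
                   pairs, ev_sigma, ev_k,
                   restr_bead, restr_k, rza, rzb,
                   force_cap, term_all_z):
    """Advance len(noise) steps in place; return step index at which the
    termination condition (all beads z > 0) fired, or -1."""
    n_steps = noise.shape[0]
    N = pos.shape[0]
    nz, nr = Ez.shape
    F = np.zeros((N, 3))
    for s in range(n_steps):
        for b in range(N):
            F[b, 0] = 0.0; F[b, 1] = 0.0; F[b, 2] = 0.0
        # bonds
        for k in range(N - 1):
            dx = pos[k + 1, 0] - pos[k, 0]
            dy = pos[k + 1, 1] - pos[k, 1]
            dz_ = pos[k + 1, 2] - pos[k, 2]
            dist = (dx * dx + dy * dy + dz_ * dz_) ** 0.5
            if dist < 1e-12:
                return -2 - k  # singular geometry, bead index encoded
            f = ks[k] * (dist - l0[k]) / dist
            F[k, 0] += f * dx; F[k, 1] += f * dy; F[k, 2] += f * dz_
            F[k + 1, 0] -= f * dx; F[k + 1, 1] -= f * dy; F[k + 1, 2] -= f * dz_
        # bending
        for i in range(1, N - 1):
            ux = pos[i, 0] - pos[i - 1, 0]
            uy = pos[i, 1] - pos[i - 1, 1]
            uz = pos[i, 2] - pos[i - 1, 2]
            vx = pos[i + 1, 0] - pos[i, 0]
            vy = pos[i + 1, 1] - pos[i, 1]
            vz = pos[i + 1, 2] - pos[i, 2]
            lu2 = ux * ux + uy * uy + uz * uz
            lv2 = vx * vx + vy * vy + vz * vz
            lu = lu2 ** 0.5; lv = lv2 ** 0.5
            inv_ulv = 1.0 / (lu * lv)
            c = (ux * vx + uy * vy + uz * vz) * inv_ulv
            k_ = kb[i]
            gux = k_ * (vx * inv_ulv - c * ux / lu2)
            guy = k_ * (vy * inv_ulv - c * uy / lu2)
            guz = k_ * (vz * inv_ulv - c * uz / lu2)
            gvx = k_ * (ux * inv_ulv - c * vx / lv2)
            gvy = k_ * (uy * inv_ulv - c * vy / lv2)
            gvz = k_ * (uz * inv_ulv - c * vz / lv2)
            F[i - 1, 0] -= gux; F[i - 1, 1] -= guy; F[i - 1, 2] -= guz
            F[i, 0] += gux - gvx; F[i, 1] += guy - gvy; F[i, 2] += guz - gvz
            F[i + 1, 0] += gvx; F[i + 1, 1] += gvy; F[i + 1, 2] += gvz
        # grid forces
        if use_field or use_steric:
            for b in range(N):
                x = pos[b, 0]; y = pos[b, 1]; zp = pos[b, 2]
                rr = (x * x + y * y) ** 0.5
                fi = (zp - z0) * idz
                fj = (rr - r0) * idr
                if fi < 0.0 or fj < 0.0 or fi > nz - 1 or fj > nr - 1:
                    continue
                i0 = int(fi); j0 = int(fj)
                if i0 > nz - 2:
                    i0 = nz - 2
                if j0 > nr - 2:
                    j0 = nr - 2
                fz_ = fi - i0; fr_ = fj - j0
                w00 = (1 - fz_) * (1 - fr_); w10 = fz_ * (1 - fr_)
                w01 = (1 - fz_) * fr_; w11 = fz_ * fr_
                fzt = 0.0; frt = 0.0
                if use_field:
                    ez = (w00 * Ez[i0, j0] + w10 * Ez[i0 + 1, j0]
                          + w01 * Ez[i0, j0 + 1] + w11 * Ez[i0 + 1, j0 + 1])
                    er = (w00 * Er[i0, j0] + w10 * Er[i0 + 1, j0]
                          + w01 * Er[i0, j0 + 1] + w11 * Er[i0 + 1, j0 + 1])
                    fzt += qpref[b] * ez
                    frt += qpref[b] * er
                if use_steric:
                    fzt += (w00 * Fsz[i0, j0] + w10 * Fsz[i0 + 1, j0]
                            + w01 * Fsz[i0, j0 + 1] + w11 * Fsz[i0 + 1, j0 + 1])
                    frt += (w00 * Fsr[i0, j0] + w10 * Fsr[i0 + 1, j0]
                            + w01 * Fsr[i0, j0 + 1] + w11 * Fsr[i0 + 1, j0 + 1])
                F[b, 2] += fzt
                if rr > 1e-12:
                    F[b, 0] += frt * x / rr
                    F[b, 1] += frt * y / rr
        # excluded volume
        for p in range(pairs.shape[0]):
            a = pairs[p, 0]; bb = pairs[p, 1]
            dx = pos[bb, 0] - pos[a, 0]
            dy = pos[bb, 1] - pos[a, 1]
            dz_ = pos[bb, 2] - pos[a, 2]
            d2 = dx * dx + dy * dy + dz_ * dz_
            if d2 < ev_sigma * ev_sigma and d2 > 1e-24:
                d = d2 ** 0.5
                f = ev_k * (ev_sigma - d) / d
                F[a, 0] -= f * dx; F[a, 1] -= f * dy; F[a, 2] -= f * dz_
                F[bb, 0] += f * dx; F[bb, 1] += f * dy; F[bb, 2] += f * dz_
        # moving restraint (along the pore axis, x = y = 0)
        if restr_bead >= 0:
            frac = s / max(n_steps - 1, 1)
            rz = rza + (rzb - rza) * frac
            F[restr_bead, 0] -= restr_k * pos[restr_bead, 0]
            F[restr_bead, 1] -= restr_k * pos[restr_bead, 1]
            F[restr_bead, 2] -= restr_k * (pos[restr_bead, 2] - rz)
        # cap, update, termination scan
        minz = 1e30
        for b in range(N):
            fmag2 = F[b, 0] ** 2 + F[b, 1] ** 2 + F[b, 2] ** 2
            if fmag2 > force_cap * force_cap:
                scale = force_cap / fmag2 ** 0.5
                F[b, 0] *= scale; F[b, 1] *= scale; F[b, 2] *= scale
            m = mob[b] * dt
            pos[b, 0] += m * F[b, 0] + sig[b] * noise[s, b, 0]
            pos[b, 1] += m * F[b, 1] + sig[b] * noise[s, b, 1]
            pos[b, 2] += m * F[b, 2] + sig[b] * noise[s, b, 2]
            if pos[b, 2] < minz:
                minz = pos[b, 2]
        if term_all_z and minz > 0.0:
            return s
    return -1


_EMPTY_GRID = np.zeros((2, 2))
_EMPTY_PAIRS = np.zeros((0, 2), dtype=np.int64)


class ChunkRunner:
    """Drives the kernel in noise chunks with neighbor-list rebuilds."""

    def __init__(self, state: ChainState, config: BDConfig,
                 grid=None, use_field: bool = False, use_steric: bool = False,
                 replicate: int = 0, scale: Optional[float] = None):
        from .chain import electrophoretic_scale
        from .units import E_FIELD_PN_PER_MV_NM
        self.state = state
        self.config = config
        # private working copy: the caller's state is never mutated
        self.pos = np.array(state.positions_nm, dtype=np.float64, order="C")
        self.rng = noise_stream(config.seed, replicate)
        kT = config.kT
        self.mob = state.diffusivity_nm2_ns / kT
        self.dt = config.dt_ns
        self.sig = np.sqrt(2.0 * state.diffusivity_nm2_ns * self.dt)
        if scale is None:
            scale = electrophoretic_scale(state.duplex)
        # kernel computes F += qpref * E with E = -grad(phi), so
        # F = -q grad(phi) * scale; charge_e is signed (negative for a
        # duplex), driving it toward the positive electrode (+z).
        self.qpref = state.charge_e * scale * E_FIELD_PN_PER_MV_NM
        self.use_field = bool(use_field and grid is not None)
        self.use_steric = bool(use_steric and grid is not None)
        if grid is not None:
            Ez, Er, Fsz, Fsr = grid.force_fields()
            self.fieldargs = (Ez, Er, Fsz, Fsr, float(grid.z_nm[0]),
                              float(grid.r_nm[0]), 1.0 / grid.dz_nm,
                              1.0 / grid.dr_nm)
        else:
            z = _EMPTY_GRID
            self.fieldargs = (z, z, z, z, 0.0, 0.0, 1.0, 1.0)
        self.steps_done = 0
        self.pairs = _EMPTY_PAIRS
        self._since_rebuild = 10 ** 9

    def _rebuild_pairs(self) -> None:
        cfg = self.config
        if not cfg.excluded_volume:
            self.pairs = _EMPTY_PAIRS
            return
        from scipy.spatial import cKDTree
        cut = cfg.ev_sigma_nm + cfg.ev_skin_nm
        tree = cKDTree(self.pos)
        raw = tree.query_pairs(cut, output_type="ndarray")
        if raw.size:
            keep = np.abs(raw[:, 0] - raw[:, 1]) >= 3
            self.pairs = np.ascontiguousarray(raw[keep], dtype=np.int64)
        else:
            self.pairs = _EMPTY_PAIRS
        self._since_rebuild = 0

    def run(self, n_steps: int, restraint=None, term_all_z: bool = False
            ) -> int:
        """Advance ``n_steps``; returns global step of termination or -1.

        ``restraint`` = (bead_index, k_pN_nm, z_from, z_to) moves a
        harmonic restraint linearly over this call.
        """
        cfg = self.config
        done = 0
        while done < n_steps:
            if self._since_rebuild >= cfg.ev_rebuild_steps:
                self._rebuild_pairs()
            chunk = min(n_steps - done,
                        cfg.ev_rebuild_steps if cfg.excluded_volume
                        else cfg.record_stride)
            noise = self.rng.standard_normal((chunk, self.pos.shape[0], 3))
            if restraint is not None:
                bead, k, za, zb = restraint
                fa = done / n_steps
                fb = (done + chunk) / n_steps
                rargs = (bead, k, za + (zb - za) * fa, za + (zb - za) * fb)
            else:
                rargs = (-1, 0.0, 0.0, 0.0)
            res = _advance_chunk(
                self.pos, noise, self.dt, self.mob, self.sig,
                self.state.rest_length_nm, self.state.k_stretch_pN_nm,
                self.state.k_bend_pN_nm, self.qpref,
                *self.fieldargs, self.use_field, self.use_steric,
                self.pairs, cfg.ev_sigma_nm, cfg.ev_k_pN_nm,
                *rargs, cfg.force_cap_pN, term_all_z)
            if res <= -2:
                raise FloatingPointError(
                    f"singular geometry at bond {-(res + 2)}")
            self._since_rebuild += chunk
            if res >= 0:
                self.steps_done += res + 1
                return self.steps_done
            done += chunk
            self.steps_done += chunk
        return -1

    def snapshot(self) -> np.ndarray:
        return self.pos.copy()
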