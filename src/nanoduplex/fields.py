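"""Electrostatic and steric potential lattices for pore geometries.

This is the package's stand-in for the original finite-element
(PNP + creeping flow) pipeline: a uniform-conductivity Laplace solve on
an axisymmetric lattice with Dirichlet electrodes at the chamber ends
and insulating (zero normal gradient) walls.  Electroosmotic screening
is not solved for; it is absorbed into the empirical 1/32 reduction
applied when converting bare-charge potential gradients to effective
forces.

Lattice convention: node-centered, phi[z_index, r_index], 0-based, with
default spacings of 10 A axially and 5 A laterally.  A steric penalty
u = k_spring * d^2 (k_spring = 4 kcal/mol/A^2, d the distance in A to
the nearest solution voxel) is defined inside the walls, and wall
voxels of the electrostatic lattice are filled by iterative neighbor
averaging so every voxel carries a value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy import ndimage

from .pore import PoreGeometry, PoreShape, build_pore
from .units import E_FIELD_PN_PER_MV_NM, KCAL_MOL_PN_NM

DEFAULT_K_SPRING_KCAL_MOL_A2 = 4.0


class SolverError(RuntimeError):
    pass


@dataclass
class PotentialGrid:
    """Axisymmetric potential/steric lattice with validity mask.

    ``phi_mV`` is defined everywhere after :func:`fill_invalid`;
    ``valid`` marks inside-solution voxels.  ``steric_kcal_mol`` is zero
    strictly inside solution and k*d^2 in the walls.
    """

    z_nm: np.ndarray            # (nz,) node axial positions
    r_nm: np.ndarray            # (nr,) node radial positions
    phi_mV: np.ndarray          # (nz, nr)
    steric_kcal_mol: np.ndarray  # (nz, nr)
    valid: np.ndarray           # (nz, nr) bool
    voltage_mV: float
    geometry: Optional[PoreGeometry] = None
    filled: bool = False
    n_outside_queries: int = 0
    _force_cache: Optional[tuple] = field(default=None, repr=False)

    @property
    def dz_nm(self) -> float:
        return float(self.z_nm[1] - self.z_nm[0])

    @property
    def dr_nm(self) -> float:
        return float(self.r_nm[1] - self.r_nm[0])

    # -- force field lattices ---------------------------------------------
    def force_fields(self):
        """(Ez, Er, Fsz, Fsr) lattices.

        Ez/Er: electric field components in mV/nm (central differences of
        the filled potential).  Fsz/Fsr: steric force per bead in pN,
        -grad(u).  Cached after first call.
        """
        if self._force_cache is None:
            if not self.filled:
                raise SolverError("fill_invalid must run before force fields")
            Ez = -np.gradient(self.phi_mV, self.z_nm, axis=0)
            Er = -np.gradient(self.phi_mV, self.r_nm, axis=1)
            u_pn_nm = self.steric_kcal_mol * KCAL_MOL_PN_NM
            Fsz = -np.gradient(u_pn_nm, self.z_nm, axis=0)
            Fsr = -np.gradient(u_pn_nm, self.r_nm, axis=1)
            self._force_cache = tuple(np.ascontiguousarray(a) for a in
                                      (Ez, Er, Fsz, Fsr))
        return self._force_cache

    # -- persistence -------------------------------------------------------
    def save_h5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("electrostatic_mV", data=self.phi_mV)
            f.create_dataset("steric_kcal_mol", data=self.steric_kcal_mol)
            f.create_dataset("valid_mask", data=self.valid)
            f.attrs["z0_nm"] = float(self.z_nm[0])
            f.attrs["r0_nm"] = float(self.r_nm[0])
            f.attrs["dz_nm"] = self.dz_nm
            f.attrs["dr_nm"] = self.dr_nm
            f.attrs["voltage_mV"] = self.voltage_mV
            f.attrs["filled"] = self.filled
            if self.geometry is not None:
                g = {k: (v.value if isinstance(v, PoreShape) else v)
                     for k, v in self.geometry.__dict__.items()}
                f.attrs["geometry_json"] = json.dumps(g)

    @classmethod
    def load_h5(cls, path) -> "PotentialGrid":
        import h5py
        with h5py.File(path, "r") as f:
            phi = f["electrostatic_mV"][...]
            steric = f["steric_kcal_mol"][...]
            valid = f["valid_mask"][...].astype(bool)
            z0, r0 = f.attrs["z0_nm"], f.attrs["r0_nm"]
            dz, dr = f.attrs["dz_nm"], f.attrs["dr_nm"]
            geometry = None
            if "geometry_json" in f.attrs:
                raw = json.loads(f.attrs["geometry_json"])
                raw["shape"] = PoreShape(raw["shape"])
                geometry = PoreGeometry(**raw)
            return cls(
                z_nm=z0 + dz * np.arange(phi.shape[0]),
                r_nm=r0 + dr * np.arange(phi.shape[1]),
                phi_mV=phi, steric_kcal_mol=steric, valid=valid,
                voltage_mV=float(f.attrs["voltage_mV"]),
                geometry=geometry, filled=bool(f.attrs["filled"]),
            )


# ---------------------------------------------------------------------------
# Laplace solver (axisymmetric, SOR, fixed sweep order)

@njit(cache=True)
def _sor_axisym(phi, solve_mask, valid, r_over_dr, inv_dz2, inv_dr2,
                omega, tol_abs, max_iter):
    nz, nr = phi.shape
    for it in range(max_iter):
        max_delta = 0.0
        for i in range(nz):
            for j in range(nr):
                if not solve_mask[i, j]:
                    continue
                num = 0.0
                den = 0.0
                # axial neighbors
                if i > 0 and valid[i - 1, j]:
                    num += inv_dz2 * phi[i - 1, j]
                    den += inv_dz2
                if i < nz - 1 and valid[i + 1, j]:
                    num += inv_dz2 * phi[i + 1, j]
                    den += inv_dz2
                # radial neighbors, metric-weighted
                if j == 0:
                    # on-axis: radial Laplacian -> 4(phi1 - phi0)/dr^2
                    if valid[i, 1]:
                        num += 4.0 * inv_dr2 * phi[i, 1]
                        den += 4.0 * inv_dr2
                else:
                    w_out = inv_dr2 * (1.0 + 0.5 / r_over_dr[j])
                    w_in = inv_dr2 * (1.0 - 0.5 / r_over_dr[j])
                    if j < nr - 1 and valid[i, j + 1]:
                        num += w_out * phi[i, j + 1]
                        den += w_out
                    if valid[i, j - 1]:
                        num += w_in * phi[i, j - 1]
                        den += w_in
                if den == 0.0:
                    continue
                new = num / den
                delta = new - phi[i, j]
                phi[i, j] += omega * delta
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol_abs:
            return it + 1, max_delta
    return -1, max_delta


def solve_potential(geometry: PoreGeometry, voltage_mV: float = 600.0,
                    dz_A: float = 10.0, dr_A: float = 5.0,
                    tol: float = 1e-6, max_iter: int = 100_000,
                    k_spring_kcal_mol_A2: float = DEFAULT_K_SPRING_KCAL_MOL_A2,
                    fill: bool = True) -> PotentialGrid:
    """Solve the Laplace potential for an axisymmetric geometry.

    The ground electrode (0 mV) sits at the cis chamber end (z_min) and
    the +voltage electrode at the far end (z_max): a negatively charged
    duplex is driven in the +z direction.  ``tol`` is relative to the
    applied voltage; exceeding ``max_iter`` raises :class:`SolverError`
    with the residual.
    """
    if geometry.shape is PoreShape.SLIT:
        raise ValueError("use solve_potential_slit for slit geometries")
    if voltage_mV <= 0:
        raise ValueError("voltage must be positive")
    dz, dr = dz_A / 10.0, dr_A / 10.0
    z = np.arange(geometry.z_min_nm, geometry.z_max_nm + dz / 2, dz)
    r = np.arange(0.0, geometry.chamber_radius_nm + dr / 2, dr)
    Z, R = np.meshgrid(z, r, indexing="ij")
    valid = np.asarray(geometry.inside_solution(R, Z))

    phi = np.zeros_like(Z)
    # Dirichlet electrodes at the two chamber ends (valid voxels only)
    phi[-1, valid[-1]] = voltage_mV
    # linear initial guess in z speeds convergence
    frac = (z - z[0]) / (z[-1] - z[0])
    phi += frac[:, None] * voltage_mV * 0.5
    phi[0, :] = 0.0
    phi[-1, valid[-1]] = voltage_mV
    phi[~valid] = 0.0

    solve_mask = valid.copy()
    solve_mask[0, :] = False
    solve_mask[-1, :] = False

    n = max(phi.shape)
    omega = 2.0 / (1.0 + np.pi / n)
    iters, resid = _sor_axisym(
        phi, solve_mask, valid, r / dr, 1.0 / dz ** 2, 1.0 / dr ** 2,
        omega, tol * voltage_mV, max_iter)
    if iters < 0:
        raise SolverError(
            f"SOR did not converge in {max_iter} sweeps "
            f"(last max update {resid:.3g} mV)")
    phi[~valid] = 0.0

    steric = steric_grid(geometry, k_spring_kcal_mol_A2, dz_A=dz_A, dr_A=dr_A,
                         _valid=valid)
    grid = PotentialGrid(z_nm=z, r_nm=r, phi_mV=phi, steric_kcal_mol=steric,
                         valid=valid, voltage_mV=voltage_mV, geometry=geometry)
    if fill:
        grid = fill_invalid(grid)
    return grid


def steric_grid(geometry: PoreGeometry,
                k_spring_kcal_mol_A2: float = DEFAULT_K_SPRING_KCAL_MOL_A2,
                dz_A: float = 10.0, dr_A: float = 5.0,
                _valid: Optional[np.ndarray] = None) -> np.ndarray:
    """Steric penalty lattice u = k * d^2 (kcal/mol), d in A to solution."""
    dz, dr = dz_A / 10.0, dr_A / 10.0
    if _valid is None:
        z = np.arange(geometry.z_min_nm, geometry.z_max_nm + dz / 2, dz)
        r = np.arange(0.0, geometry.chamber_radius_nm + dr / 2, dr)
        Z, R = np.meshgrid(z, r, indexing="ij")
        _valid = np.asarray(geometry.inside_solution(R, Z))
    # anisotropic Euclidean distance (A) from wall voxels to nearest solution
    d_A = ndimage.distance_transform_edt(~_valid, sampling=(dz_A, dr_A))
    return k_spring_kcal_mol_A2 * d_A ** 2


def fill_invalid(grid: PotentialGrid) -> PotentialGrid:
    """Fill wall voxels of the potential by iterative neighbor averaging.

    Each pass assigns, to every still-unfilled voxel with at least one
    valid-or-filled 4-neighbor, the arithmetic mean of those neighbors.
    Valid voxels are never modified; the operation is idempotent.
    """
    phi = grid.phi_mV.copy()
    done = grid.valid.copy()
    if not done.any():
        raise SolverError("cannot fill an all-invalid grid")
    nz, nr = phi.shape
    max_pass = nz + nr
    for _ in range(max_pass):
        if done.all():
            break
        ssum = np.zeros_like(phi)
        cnt = np.zeros_like(phi)
        for shift, axis in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
            nb_phi = np.roll(phi, shift, axis=axis)
            nb_done = np.roll(done, shift, axis=axis)
            # roll wraps around; invalidate wrapped entries
            if axis == 0:
                sl = 0 if shift == 1 else -1
                nb_done = nb_done.copy()
                nb_done[sl, :] = False
            else:
                sl = 0 if shift == 1 else -1
                nb_done = nb_done.copy()
                nb_done[:, sl] = False
            ssum += np.where(nb_done, nb_phi, 0.0)
            cnt += nb_done
        frontier = (~done) & (cnt > 0)
        phi[frontier] = ssum[frontier] / cnt[frontier]
        done |= frontier
    if not done.all():
        raise SolverError("disconnected voxels could not be filled")
    return PotentialGrid(z_nm=grid.z_nm, r_nm=grid.r_nm, phi_mV=phi,
                         steric_kcal_mol=grid.steric_kcal_mol,
                         valid=grid.valid, voltage_mV=grid.voltage_mV,
                         geometry=grid.geometry, filled=True)


# ---------------------------------------------------------------------------
# force evaluation

def _bilinear(a: np.ndarray, iz: float, jr: float) -> float:
    i0 = int(np.floor(iz)); j0 = int(np.floor(jr))
    i0 = min(max(i0, 0), a.shape[0] - 2)
    j0 = min(max(j0, 0), a.shape[1] - 2)
    fz = iz - i0; fr = jr - j0
    return ((1 - fz) * (1 - fr) * a[i0, j0] + fz * (1 - fr) * a[i0 + 1, j0]
            + (1 - fz) * fr * a[i0, j0 + 1] + fz * fr * a[i0 + 1, j0 + 1])


def effective_force(grid: PotentialGrid, position_nm, charge_e: float,
                    scale: float) -> np.ndarray:
    """Effective electrophoretic force F = -q grad(phi) * scale, pN.

    ``charge_e`` is the signed charge in elementary units (a duplex bead
    carries negative charge).  ``scale`` is the electroosmotic reduction
    factor (1/32 for the B-form reference; A-like beads additionally
    carry the all-atom force-per-length ratio, see
    :func:`nanoduplex.chain.electrophoretic_scale`).  Positions outside
    the lattice are treated as far field: zero force, counted on
    ``grid.n_outside_queries``.
    """
    x, y, zp = (float(v) for v in position_nm)
    r = float(np.hypot(x, y))
    z0, r0 = grid.z_nm[0], grid.r_nm[0]
    iz = (zp - z0) / grid.dz_nm
    jr = (r - r0) / grid.dr_nm
    if not (0 <= iz <= grid.phi_mV.shape[0] - 1
            and 0 <= jr <= grid.phi_mV.shape[1] - 1):
        grid.n_outside_queries += 1
        return np.zeros(3)
    Ez, Er, _, _ = grid.force_fields()
    fz = charge_e * scale * _bilinear(Ez, iz, jr) * E_FIELD_PN_PER_MV_NM
    fr = charge_e * scale * _bilinear(Er, iz, jr) * E_FIELD_PN_PER_MV_NM
    if r > 1e-12:
        return np.array([fr * x / r, fr * y / r, fz])
    return np.array([0.0, 0.0, fz])


def solved_resistance(grid: PotentialGrid,
                      conductivity_nS_nm: float) -> float:
    """Open-pore resistance (1/nS) implied by the solved field.

    The total current is the flux of sigma * (-dphi/dz) through
    cross-sections inside the confined region, averaged over planes to
    suppress discretization noise.
    """
    Ez, _, _, _ = grid.force_fields()
    zlo, zhi = grid.geometry.pore_z_range_nm
    sel = np.where((grid.z_nm > zlo + grid.dz_nm)
                   & (grid.z_nm < zhi - grid.dz_nm))[0]
    if sel.size == 0:
        sel = np.array([len(grid.z_nm) // 2])
    r = grid.r_nm
    currents = []
    for i in sel:
        integrand = np.where(grid.valid[i], Ez[i], 0.0) * 2 * np.pi * r
        currents.append(conductivity_nS_nm * np.trapezoid(integrand, r))
    current_pA = float(abs(np.mean(currents)))
    if current_pA <= 0:
        raise SolverError("non-positive current from solved field")
    return grid.voltage_mV / current_pA


# ---------------------------------------------------------------------------
# slit (3-D Cartesian) variant

@njit(cache=True)
def _sor_cart3d(phi, solve_mask, valid, w, omega, tol_abs, max_iter):
    nx, ny, nz = phi.shape
    for it in range(max_iter):
        max_delta = 0.0
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not solve_mask[i, j, k]:
                        continue
                    num = 0.0
                    den = 0.0
                    for di, dj, dk, ww in ((1, 0, 0, w[0]), (-1, 0, 0, w[0]),
                                           (0, 1, 0, w[1]), (0, -1, 0, w[1]),
                                           (0, 0, 1, w[2]), (0, 0, -1, w[2])):
                        ii, jj, kk = i + di, j + dj, k + dk
                        if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz \
                                and valid[ii, jj, kk]:
                            num += ww * phi[ii, jj, kk]
                            den += ww
                    if den == 0.0:
                        continue
                    delta = num / den - phi[i, j, k]
                    phi[i, j, k] += omega * delta
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
        if max_delta < tol_abs:
            return it + 1, max_delta
    return -1, max_delta


def solve_potential_slit(geometry: PoreGeometry, voltage_mV: float = 600.0,
                         spacing_A: float = 20.0, tol: float = 1e-5,
                         max_iter: int = 50_000):
    """Laplace solve for the slit on a 3-D Cartesian lattice.

    Same boundary rules as the axisymmetric solver (Dirichlet chamber
    ends along z, insulating walls).  Returns (x, y, z, phi, valid).
    Intended for small lattices; the slit has no default dimensions.
    """
    if geometry.shape is not PoreShape.SLIT:
        raise ValueError("geometry must be a slit")
    h = spacing_A / 10.0
    L = geometry.chamber_radius_nm
    x = np.arange(-L, L + h / 2, h)
    y = np.arange(-L, L + h / 2, h)
    z = np.arange(geometry.z_min_nm, geometry.z_max_nm + h / 2, h)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    valid = np.asarray(geometry.inside_solution_slit(X, Y, Z))
    phi = np.where(valid, (Z - z[0]) / (z[-1] - z[0]) * voltage_mV * 0.5, 0.0)
    phi[:, :, -1] = np.where(valid[:, :, -1], voltage_mV, 0.0)
    phi[:, :, 0] = 0.0
    solve_mask = valid.copy()
    solve_mask[:, :, 0] = False
    solve_mask[:, :, -1] = False
    omega = 2.0 / (1.0 + np.pi / max(phi.shape))
    w = np.array([1.0, 1.0, 1.0]) / h ** 2
    iters, resid = _sor_cart3d(phi, solve_mask, valid, w, omega,
                               tol * voltage_mV, max_iter)
    if iters < 0:
        raise SolverError(f"slit SOR did not converge (residual {resid:.3g})")
    return x, y, z, phi, valid


# ---------------------------------------------------------------------------
# analytic oracles

def conical_resistance_analytic(geometry: PoreGeometry,
                                conductivity_nS_nm: float,
                                dz_nm: float = 0.25) -> float:
    """Series-slab resistance of the confined region plus access terms.

    R = sum dz/(sigma A(z)) over the pore interval + 1/(4 sigma r) per
    entrance; for a perfect cone the slab sum converges to
    L/(sigma pi r_tip r_base).
    """
    zlo, zhi = geometry.pore_z_range_nm
    zc = np.arange(zlo + dz_nm / 2, zhi, dz_nm)
    rw = np.asarray(geometry.wall_radius(zc))
    R = np.sum(dz_nm / (conductivity_nS_nm * np.pi * rw ** 2))
    r_ends = (float(geometry.wall_radius(zlo + 1e-9)),
              float(geometry.wall_radius(zhi - 1e-9)))
    for re in r_ends:
        R += 1.0 / (4.0 * conductivity_nS_nm * re)
    return float(R)
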