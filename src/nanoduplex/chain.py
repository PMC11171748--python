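"""Coarse-grained bead-spring duplex chains.

A duplex of ``n_bp`` base pairs is represented by a linear chain of
beads at ``bp_per_bead`` resolution.  Constants are mapped so that the
chain conserves, at any resolution:

* contour length      rest length = rise * bp_per_bead
* stretch modulus     k_stretch = elastic_pN / rest_length
* persistence length  k_bend = Lp * kT / rest_length  (discrete
  worm-like chain, bending energy k_bend * (1 - cos theta) per joint)
* line charge         2 e per bp, carried as negative charge
* friction per length (free-draining: per-bead friction =
  friction_per_length * rest_length; A-like beads additionally carry
  the hydrostatic ``mobility_scale``)

The helical two-strand structure is collapsed onto the linear chain;
pitch enters only through :class:`~nanoduplex.theory.DuplexSpec`
bookkeeping (the torsional degree of freedom is assumed relaxed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .theory import DuplexSpec, rod_friction
from .units import kT as _kT

#: Electroosmotic reduction of the bare electrophoretic force.
EFFECTIVE_FORCE_FACTOR = 1.0 / 32.0

#: B-form reference values for the per-unit-length force scaling.
_B_FORCE_PER_LENGTH = 20.98
_B_RISE_NM = 0.34


def electrophoretic_scale(duplex: DuplexSpec) -> float:
    """Per-bead scale converting bare-charge potential forces to
    effective forces.

    The B-form reference is 1/32.  Other forms are scaled so that the
    *force per unit contour length* ratio matches the all-atom
    force-per-length ratio (19.47/20.98 for the A-like hybrid): because
    beads sit at the form's own rise, the per-bead factor carries an
    extra rise ratio.
    """
    return (EFFECTIVE_FORCE_FACTOR
            * (duplex.force_per_length_pN_nm / _B_FORCE_PER_LENGTH)
            * (duplex.rise_nm / _B_RISE_NM))


@dataclass
class ChainState:
    """Bead-chain configuration plus per-bead/per-bond constants."""

    positions_nm: np.ndarray      # (N, 3)
    rest_length_nm: np.ndarray    # (N-1,)
    k_stretch_pN_nm: np.ndarray   # (N-1,) pN/nm
    k_bend_pN_nm: np.ndarray      # (N,) pN nm, interior beads only used
    charge_e: np.ndarray          # (N,) signed, negative for nucleic acid
    diffusivity_nm2_ns: np.ndarray  # (N,)
    duplex: DuplexSpec
    bp_per_bead: int
    n_bp: int

    @property
    def n_beads(self) -> int:
        return self.positions_nm.shape[0]

    @property
    def contour_nm(self) -> float:
        return float(self.rest_length_nm.sum())

    def copy(self) -> "ChainState":
        return replace(self, positions_nm=self.positions_nm.copy())


def build_chain(duplex: DuplexSpec, n_bp: int, bp_per_bead: int = 5,
                friction_per_length_pN_ns_nm2: Optional[float] = None,
                temperature_K: float = 291.0,
                viscosity_pN_ns_nm2: float = 1.06) -> ChainState:
    """Build a straight chain along +z with mapped CG constants.

    If ``friction_per_length`` is not given it is taken from the
    slender-body rod friction of the full contour, gamma(L)/L, which
    sets free-draining per-bead diffusivities consistent with the
    closed-form hydrodynamic estimates.
    """
    if bp_per_bead <= 0:
        raise ValueError("bp_per_bead must be positive")
    if n_bp < 2 * bp_per_bead:
        raise ValueError("need at least two beads worth of base pairs")
    n_beads = math.ceil(n_bp / bp_per_bead)
    l0 = duplex.rise_nm * bp_per_bead
    kT = _kT(temperature_K)

    contour = n_bp * duplex.rise_nm
    if friction_per_length_pN_ns_nm2 is None:
        friction_per_length_pN_ns_nm2 = rod_friction(
            contour, duplex.radius_nm, viscosity_pN_ns_nm2) / contour
    zeta_bead = friction_per_length_pN_ns_nm2 * l0
    D = kT / zeta_bead * duplex.mobility_scale

    positions = np.zeros((n_beads, 3))
    positions[:, 2] = np.arange(n_beads) * l0

    rest = np.full(n_beads - 1, l0)
    k_s = np.full(n_beads - 1, duplex.elastic_pN / l0)
    k_b = np.full(n_beads, duplex.persistence_nm * kT / l0)

    charge = np.full(n_beads, -duplex.charge_per_bp * bp_per_bead)
    rem = n_bp - (n_beads - 1) * bp_per_bead
    charge[-1] = -duplex.charge_per_bp * rem

    return ChainState(
        positions_nm=positions, rest_length_nm=rest, k_stretch_pN_nm=k_s,
        k_bend_pN_nm=k_b, charge_e=charge,
        diffusivity_nm2_ns=np.full(n_beads, D),
        duplex=duplex, bp_per_bead=bp_per_bead, n_bp=n_bp)


# ---------------------------------------------------------------------------
# internal (bonded) energies and forces

def chain_energy(state: ChainState, positions: Optional[np.ndarray] = None
                 ) -> float:
    """Stretch + bending energy, pN nm."""
    x = state.positions_nm if positions is None else positions
    b = np.diff(x, axis=0)
    blen = np.linalg.norm(b, axis=1)
    if np.any(blen < 1e-12):
        raise FloatingPointError("coincident consecutive beads")
    e_stretch = 0.5 * np.sum(state.k_stretch_pN_nm
                             * (blen - state.rest_length_nm) ** 2)
    t = b / blen[:, None]
    cos_t = np.sum(t[:-1] * t[1:], axis=1)
    e_bend = np.sum(state.k_bend_pN_nm[1:-1] * (1.0 - cos_t))
    return float(e_stretch + e_bend)


def internal_forces(state: ChainState,
                    positions: Optional[np.ndarray] = None) -> np.ndarray:
    """Bonded forces -grad(E), pN; the total sums to zero."""
    x = state.positions_nm if positions is None else positions
    n = x.shape[0]
    F = np.zeros_like(x)
    b = np.diff(x, axis=0)
    blen = np.linalg.norm(b, axis=1)
    if np.any(blen < 1e-12):
        raise FloatingPointError("coincident consecutive beads")
    bhat = b / blen[:, None]

    # stretch
    f = (state.k_stretch_pN_nm * (blen - state.rest_length_nm))[:, None] * bhat
    F[:-1] += f
    F[1:] -= f

    # bending: U_i = k_b (1 - cos theta_i) at interior beads
    u = b[:-1]; v = b[1:]
    lu = blen[:-1][:, None]; lv = blen[1:][:, None]
    c = np.sum(bhat[:-1] * bhat[1:], axis=1)[:, None]
    dc_du = v / (lu * lv) - c * u / lu ** 2
    dc_dv = u / (lu * lv) - c * v / lv ** 2
    kb = state.k_bend_pN_nm[1:-1][:, None]
    F[:-2] += -kb * dc_du
    F[1:-1] += kb * dc_du - kb * dc_dv
    F[2:] += kb * dc_dv
    return F


# ---------------------------------------------------------------------------
# worm-like-chain warm starts

def wlc_positions(n_beads: int, l0_nm: float, lp_nm: float,
                  rng: np.random.Generator,
                  start=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0)
                  ) -> np.ndarray:
    """Equilibrium sample of the discrete worm-like chain.

    Joint angles are drawn from the exact Boltzmann density
    p(cos t) ~ exp(beta k cos t) with beta k = lp/l0, bonds at rest
    length; the result is an unbiased equilibrium configuration of the
    ideal (phantom) chain and serves as a warm start for BD runs.
    """
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    kappa = lp_nm / l0_nm
    t = np.zeros((n_beads - 1, 3))
    t[0] = np.asarray(direction, float)
    t[0] /= np.linalg.norm(t[0])
    # inverse-CDF sample of u = cos(theta): p(u) ~ exp(kappa u) on [-1, 1]
    xi = rng.random(n_beads - 2)
    if kappa > 1e-12:
        u = 1.0 + np.log(xi + (1.0 - xi) * np.exp(-2.0 * kappa)) / kappa
    else:
        u = 2.0 * xi - 1.0
    phi = rng.random(n_beads - 2) * 2.0 * np.pi
    for i in range(1, n_beads - 1):
        prev = t[i - 1]
        # orthonormal frame around prev
        a = np.array([1.0, 0.0, 0.0])
        if abs(prev[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(prev, a); e1 /= np.linalg.norm(e1)
        e2 = np.cross(prev, e1)
        s = math.sqrt(max(0.0, 1.0 - u[i - 1] ** 2))
        t[i] = (u[i - 1] * prev
                + s * (math.cos(phi[i - 1]) * e1 + math.sin(phi[i - 1]) * e2))
        t[i] /= np.linalg.norm(t[i])
    x = np.empty((n_beads, 3))
    x[0] = start
    x[1:] = np.asarray(start) + np.cumsum(t * l0_nm, axis=0)
    return x


def wlc_end_to_end_sq(contour_nm: float, lp_nm: float) -> float:
    """Closed-form <R^2> of the worm-like chain."""
    L, lp = contour_nm, lp_nm
    return 2.0 * lp * L - 2.0 * lp ** 2 * (1.0 - math.exp(-L / lp))
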