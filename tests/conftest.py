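"""Shared fixtures: desk-scale grids and duplex parameter sets.

Grids are solved once per session on a coarsened lattice (20 A x 10 A)
with reduced chambers; this changes absolute currents by a few percent
but none of the directional physics the tests assert.
"""

import numpy as np
import pytest

from nanoduplex.fields import solve_potential
from nanoduplex.pore import build_pore
from nanoduplex.theory import a_like, b_form


@pytest.fixture(scope="session")
def dd_spec():
    return b_form()


@pytest.fixture(scope="session")
def rd_spec():
    return a_like()


@pytest.fixture(scope="session")
def desk_conical_geometry():
    return build_pore("conical_pipette", chamber_length_nm=120,
                      chamber_radius_nm=100)


@pytest.fixture(scope="session")
def desk_conical_grid(desk_conical_geometry):
    return solve_potential(desk_conical_geometry, 600.0, dz_A=20, dr_A=10)


@pytest.fixture(scope="session")
def desk_cylinder_grid():
    geo = build_pore("cylinder", aperture_radius_nm=5,
                     membrane_thickness_nm=30, chamber_length_nm=80,
                     chamber_radius_nm=80)
    return solve_potential(geo, 600.0, dz_A=20, dr_A=10)


@pytest.fixture(scope="session")
def desk_hourglass_grid():
    geo = build_pore("hourglass", aperture_radius_nm=5,
                     taper_angle_deg_near=20.0, membrane_thickness_nm=30,
                     chamber_length_nm=80, chamber_radius_nm=80)
    return solve_potential(geo, 600.0, dz_A=20, dr_A=10)
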