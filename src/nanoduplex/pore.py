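"""Pore geometries: conical glass nanopipette, cylinder, hourglass, slit.

Coordinate convention (axisymmetric shapes): cylindrical (r, z) with the
narrowest cross-section of the pore at z = 0 and z increasing from the
cis chamber (molecule entry side, negative z) toward trans.  For the
nanopipette the "trans" side is the pipette interior (z > 0, walls
widening with z); for membrane pores the membrane straddles z = 0.

The slit is a genuinely 3-D geometry (rectangular opening in a membrane)
and has no default dimensions; it must be fully configured.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


class PoreShape(str, enum.Enum):
    CONICAL_PIPETTE = "conical_pipette"
    CYLINDER = "cylinder"
    HOURGLASS = "hourglass"
    SLIT = "slit"


@dataclass(frozen=True)
class PoreGeometry:
    """Axisymmetric pore description (plus slit parameters).

    Defaults describe the measured nanopipette: 5 nm aperture radius,
    4.87 deg taper for the first 50 nm, 1.2 deg beyond, 300 nm pipette,
    300 nm x 150 nm solution chambers.  ``wall_charge_C_m2`` is carried
    as metadata only (the potential solver treats walls as insulating).
    """

    shape: PoreShape = PoreShape.CONICAL_PIPETTE
    aperture_radius_nm: float = 5.0
    taper_angle_deg_near: float = 4.87
    taper_near_extent_nm: float = 50.0
    taper_angle_deg_far: float = 1.2
    pipette_length_nm: float = 300.0
    chamber_length_nm: float = 300.0
    chamber_radius_nm: float = 150.0
    membrane_thickness_nm: float = 30.0
    slit_width_nm: Optional[float] = None
    slit_height_nm: Optional[float] = None
    wall_charge_C_m2: float = -0.01

    def __post_init__(self) -> None:
        if self.aperture_radius_nm <= 0:
            raise ValueError("aperture radius must be positive")
        for name in ("pipette_length_nm", "chamber_length_nm",
                     "chamber_radius_nm", "membrane_thickness_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.aperture_radius_nm >= self.chamber_radius_nm:
            raise ValueError("aperture cannot be wider than the chamber")
        if self.shape is PoreShape.SLIT:
            if not self.slit_width_nm or not self.slit_height_nm:
                raise ValueError("slit geometry requires slit_width_nm and "
                                 "slit_height_nm (no defaults)")
        if self.shape is PoreShape.CONICAL_PIPETTE:
            r_end = self.wall_radius(self.pipette_length_nm)
            if r_end > self.chamber_radius_nm:
                raise ValueError("pipette widens beyond the chamber radius")

    # -- axial extent of the solution domain -------------------------------
    @property
    def z_min_nm(self) -> float:
        if self.shape is PoreShape.CONICAL_PIPETTE:
            return -self.chamber_length_nm
        return -self.membrane_thickness_nm / 2 - self.chamber_length_nm

    @property
    def z_max_nm(self) -> float:
        if self.shape is PoreShape.CONICAL_PIPETTE:
            return self.pipette_length_nm
        return self.membrane_thickness_nm / 2 + self.chamber_length_nm

    def wall_radius(self, z_nm):
        """Radius of the solution domain at height z (piecewise linear).

        Vectorized over z.  Outside the membrane/pipette the chamber
        radius is returned.
        """
        z = np.asarray(z_nm, dtype=float)
        R = np.full_like(z, self.chamber_radius_nm)
        if self.shape is PoreShape.CONICAL_PIPETTE:
            near = np.clip(z, 0.0, self.taper_near_extent_nm)
            far = np.clip(z - self.taper_near_extent_nm, 0.0, None)
            r_in = (self.aperture_radius_nm
                    + near * math.tan(math.radians(self.taper_angle_deg_near))
                    + far * math.tan(math.radians(self.taper_angle_deg_far)))
            R = np.where(z >= 0.0, np.minimum(r_in, self.chamber_radius_nm), R)
        elif self.shape is PoreShape.CYLINDER:
            half = self.membrane_thickness_nm / 2
            R = np.where(np.abs(z) <= half, self.aperture_radius_nm, R)
        elif self.shape is PoreShape.HOURGLASS:
            half = self.membrane_thickness_nm / 2
            slope = math.tan(math.radians(self.taper_angle_deg_near))
            r_in = self.aperture_radius_nm + np.abs(z) * slope
            R = np.where(np.abs(z) <= half,
                         np.minimum(r_in, self.chamber_radius_nm), R)
        elif self.shape is PoreShape.SLIT:
            raise ValueError("slit geometry has no axisymmetric wall profile")
        return R if R.ndim else float(R)

    def inside_solution(self, r_nm, z_nm):
        """Boolean predicate: is (r, z) occupied by electrolyte?"""
        r = np.asarray(r_nm, dtype=float)
        z = np.asarray(z_nm, dtype=float)
        in_z = (z >= self.z_min_nm) & (z <= self.z_max_nm)
        return in_z & (r <= self.wall_radius(z))

    def inside_solution_slit(self, x_nm, y_nm, z_nm):
        """3-D predicate for the slit: rectangular channel in a membrane.

        x spans the slit width, y the slit height, membrane straddles
        z = 0; the chambers are full boxes on either side.
        """
        if self.shape is not PoreShape.SLIT:
            raise ValueError("only valid for slit geometry")
        x = np.asarray(x_nm, float)
        y = np.asarray(y_nm, float)
        z = np.asarray(z_nm, float)
        half = self.membrane_thickness_nm / 2
        in_membrane = np.abs(z) <= half
        in_channel = (np.abs(x) <= self.slit_width_nm / 2) & \
                     (np.abs(y) <= self.slit_height_nm / 2)
        in_chamber = (np.abs(z) > half) & (np.abs(z) <= self.z_max_nm) & \
                     (np.abs(x) <= self.chamber_radius_nm) & \
                     (np.abs(y) <= self.chamber_radius_nm)
        return (in_membrane & in_channel) | in_chamber

    # -- pore axial range used by the current calculators ------------------
    @property
    def pore_z_range_nm(self) -> tuple[float, float]:
        """Axial interval over which the wall confines the solution."""
        if self.shape is PoreShape.CONICAL_PIPETTE:
            return (0.0, self.pipette_length_nm)
        half = self.membrane_thickness_nm / 2
        return (-half, half)


_SHAPE_ALIASES = {"conical": PoreShape.CONICAL_PIPETTE,
                  "pipette": PoreShape.CONICAL_PIPETTE,
                  "nanopipette": PoreShape.CONICAL_PIPETTE}


def build_pore(shape: PoreShape | str = PoreShape.CONICAL_PIPETTE,
               **overrides) -> PoreGeometry:
    """Construct a validated pore geometry with defaults per shape."""
    if isinstance(shape, str) and shape in _SHAPE_ALIASES:
        shape = _SHAPE_ALIASES[shape]
    shape = PoreShape(shape)
    return PoreGeometry(shape=shape, **overrides)
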