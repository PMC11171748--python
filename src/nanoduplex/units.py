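"""Internal unit system and physical constants.

Everything inside the package is expressed in pN, nm, ns, elementary
charge (e), mV and K.  Convenient consequences:

* energy unit  = pN nm  (1 kT at 291 K is about 4.017 pN nm)
* diffusivity  = nm^2 / ns  (1 nm^2/ns = 1e-9 m^2/s)
* conductivity = nS / nm (1 S/m = 1 nS/nm), current = nS * mV = pA
* e * (1 mV/nm) = 0.1602... pN

Public I/O (file formats, CLI) states units explicitly in names.
"""

from __future__ import annotations

#: Boltzmann constant, pN nm / K.
KB_PN_NM_PER_K = 1.380649e-2

#: 1 kcal/mol in pN nm.
KCAL_MOL_PN_NM = 6.947695

#: Force (pN) on one elementary charge in a 1 mV/nm field.
E_FIELD_PN_PER_MV_NM = 0.1602176634

#: Conversion from mS/cm to nS/nm (1 mS/cm = 0.1 S/m = 0.1 nS/nm).
MS_CM_TO_NS_NM = 0.1

#: Default bath temperature, K.
DEFAULT_TEMPERATURE_K = 291.0


def kT(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in pN nm at the given temperature."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return KB_PN_NM_PER_K * temperature_K
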