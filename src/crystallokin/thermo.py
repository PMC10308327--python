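"""Thermodynamic bookkeeping for nanotip-localized crystallization.

The driving force for the phase transition is the chemical potential
difference dmu = k_B * T * ln(A_D / A_E), with A_D the activity of the
analyte and A_E its activity at equilibrium (the solubility); concentrations
stand in for activities in the usual approximation.  The supersaturation is
sigma = ln(C_tip / C_eq) for the local concentration at the nanotip against
saturation.  A Faradaic bookkeeping converts a measured current over time in
a given volume to the transported-charge equivalent concentration change.
"""

from __future__ import annotations

import math

from scipy.constants import Boltzmann as K_B
from scipy.constants import physical_constants

__all__ = ["K_B", "FARADAY", "chemical_potential", "supersaturation",
           "charge_to_concentration"]

FARADAY: float = physical_constants["Faraday constant"][0]  # C/mol


def chemical_potential(A_D: float, A_E: float, T: float) -> float:
    """Driving force dmu = k_B * T * ln(A_D / A_E), in joules per molecule.

    Positive when the analyte activity exceeds its equilibrium value
    (supersaturated), zero at equilibrium, negative when undersaturated.
    """
    if A_D <= 0 or A_E <= 0 or T <= 0:
        raise ValueError("activities and temperature must be positive")
    return K_B * T * math.log(A_D / A_E)


def supersaturation(C_tip: float, C_eq: float) -> float:
    """Supersaturation sigma = ln(C_tip / C_eq), dimensionless."""
    if C_tip <= 0 or C_eq <= 0:
        raise ValueError("concentrations must be positive")
    return math.log(C_tip / C_eq)


def charge_to_concentration(current: float, duration: float, volume: float,
                            charge_number: float = 1) -> float:
    """Concentration change equivalent to the transported charge, in mol/L.

    dC = (I * t) / (z * F * V) with I in amperes, t in seconds, V in litres.
    E.g. 2 nA over 1 h in 20 uL at z = 1 is ~3.7e-6 M — orders of magnitude
    below typical bulk concentrations, so the measurement does not perturb
    the bulk.
    """
    if current < 0 or duration < 0:
        raise ValueError("current and duration must be non-negative")
    if volume <= 0 or charge_number <= 0:
        raise ValueError("volume and charge_number must be positive")
    return (current * duration) / (charge_number * FARADAY * volume)
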