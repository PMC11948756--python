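"""Physical constants, solvent properties and amino-acid tables.

Canonical internal units: concentrations in µM, times in seconds (lag times
in µs where noted), temperatures in °C, lengths in Å, masses in Da/kDa.
"""

from __future__ import annotations

import numpy as np

AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN = 1.380649e-23  # J/K
CELSIUS_OFFSET = 273.15

#: Average (isotope-averaged) masses of the free amino acids, Da.
#: Chain mass = sum(free masses) - (N-1) * water.
AMINO_ACID_MASS_DA = {
    "A": 89.0932, "R": 174.2010, "N": 132.1179, "D": 133.1027,
    "C": 121.1582, "E": 147.1293, "Q": 146.1445, "G": 75.0666,
    "H": 155.1546, "I": 131.1729, "L": 131.1729, "K": 146.1876,
    "M": 149.2113, "F": 165.1891, "P": 115.1305, "S": 105.0926,
    "T": 119.1192, "W": 204.2252, "Y": 181.1885, "V": 117.1463,
}

WATER_MASS_DA = 18.01528

#: Mass increment per amide hydrogen replaced by deuterium, Da.
DEUTERIUM_MASS_INCREMENT_DA = 1.00628

#: Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "E": -3.5, "Q": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Dynamic viscosity of pure water, mPa*s, vs temperature in °C
# (IAPWS-consistent tabulation; linear interpolation between entries).
_WATER_VISCOSITY_TABLE = np.array([
    (0.0, 1.7914), (5.0, 1.5188), (10.0, 1.3060), (15.0, 1.1375),
    (20.0, 1.0016), (21.0, 0.9775), (22.0, 0.9544), (23.0, 0.9321),
    (24.0, 0.9107), (25.0, 0.8900), (30.0, 0.7972), (35.0, 0.7190),
    (37.0, 0.6913), (40.0, 0.6527), (50.0, 0.5465), (60.0, 0.4660),
    (70.0, 0.4035), (80.0, 0.3540), (90.0, 0.3142), (100.0, 0.2816),
])


def water_viscosity_mpas(temperature_c: float) -> float:
    """Viscosity of pure water at ``temperature_c`` in mPa*s.

    Linear interpolation in a fixed published table; raises for
    temperatures outside 0-100 °C.
    """
    t = float(temperature_c)
    tab = _WATER_VISCOSITY_TABLE
    if not (tab[0, 0] <= t <= tab[-1, 0]):
        raise ValueError(f"temperature {t} °C outside tabulated range 0-100 °C")
    return float(np.interp(t, tab[:, 0], tab[:, 1]))
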