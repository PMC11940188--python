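"""Physical constants and per-element parameters shared across the package.

Scattering-length bookkeeping follows the dummy-atom convention used for
protein solution scattering: each non-hydrogen atom carries its vacuum
electron count and a displaced-solvent volume, and the excess scattering
length is (Z - rho_solvent * V) * r_e.
"""

from __future__ import annotations

#: Gas constant, J mol^-1 K^-1 (used by every unfolding model).
R_GAS = 8.314

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Thomson scattering length of the electron, cm.
R_ELECTRON_CM = 2.8179403262e-13

#: Electron density of water, e / A^3.
WATER_ELECTRON_DENSITY = 0.334

#: Excess scattering length density per unit mass for proteins, cm / g.
PROTEIN_DRHO_M = 2.0e10

#: van der Waals radii, A (Bondi-style table; fallback 1.7).
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "FE": 2.00,
    "ZN": 1.39,
    "CA": 2.31,
    "NA": 2.27,
    "MG": 1.73,
    "CL": 1.75,
}

#: Electron counts for the elements that occur in protein models.
ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15,
    "SE": 34, "FE": 26, "ZN": 30, "CA": 20, "NA": 11, "MG": 12, "CL": 17,
}

#: Displaced-solvent volumes, A^3 (Fraser-style excluded volumes).
DISPLACED_VOLUMES = {
    "H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "S": 19.86, "P": 5.73,
    "SE": 9.0, "FE": 7.99, "ZN": 9.85, "CA": 31.89, "NA": 4.45, "MG": 21.69,
    "CL": 28.81,
}

#: Atomic masses, Da.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "CA": 40.078,
    "NA": 22.990, "MG": 24.305, "CL": 35.45,
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), 1.70)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 12.011)
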