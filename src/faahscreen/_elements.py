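"""Per-element constants used as descriptor weights.

Values cover the organic element set of this pipeline. Weights enter the
descriptors relative to carbon (mass / 12.011, Sanderson electronegativity /
2.746, first ionization energy / 11.260 eV, van der Waals volume as
(r / 1.70)^3 from Bondi radii).
"""

from __future__ import annotations

#: Sanderson electronegativities.
SANDERSON_EN = {
    1: 2.592,   # H
    5: 2.275,   # B
    6: 2.746,   # C
    7: 3.194,   # N
    8: 3.654,   # O
    9: 4.000,   # F
    14: 2.138,  # Si
    15: 2.515,  # P
    16: 2.957,  # S
    17: 3.475,  # Cl
    34: 3.014,  # Se
    35: 3.219,  # Br
    53: 2.778,  # I
}

#: First ionization energies, eV.
IONIZATION_EV = {
    1: 13.598,
    5: 8.298,
    6: 11.260,
    7: 14.534,
    8: 13.618,
    9: 17.423,
    14: 8.152,
    15: 10.487,
    16: 10.360,
    17: 12.968,
    34: 9.752,
    35: 11.814,
    53: 10.451,
}

#: Bondi van der Waals radii, Angstrom.
VDW_RADIUS = {
    1: 1.20,
    5: 1.92,
    6: 1.70,
    7: 1.55,
    8: 1.52,
    9: 1.47,
    14: 2.10,
    15: 1.80,
    16: 1.80,
    17: 1.75,
    34: 1.90,
    35: 1.85,
    53: 1.98,
}

CARBON_MASS = 12.011
CARBON_EN = SANDERSON_EN[6]
CARBON_IONIZATION = IONIZATION_EV[6]
CARBON_VDW_VOLUME = VDW_RADIUS[6] ** 3


def relative_en(z: int) -> float:
    return SANDERSON_EN[z] / CARBON_EN


def relative_ionization(z: int) -> float:
    return IONIZATION_EV[z] / CARBON_IONIZATION


def relative_vdw_volume(z: int) -> float:
    return VDW_RADIUS[z] ** 3 / CARBON_VDW_VOLUME
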