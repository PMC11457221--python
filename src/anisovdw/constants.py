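"""Geometry and van der Waals constants.

All distances are in angstroms, angles in degrees, energies in kJ/mol.

The van der Waals radii are the Bondi compilation (J. Phys. Chem. 68, 441,
1964); iodine (1.98 A), helium (1.40 A) and oxygen (1.52 A) in particular are
Bondi values. Covalent bond lengths are standard experimental equilibrium
values for the gas-phase diatomics and the water monomer. Everything here is
a default: the builder functions accept overrides, and the CLI accepts a
TOML/YAML configuration file (see :mod:`anisovdw.config`).
"""

from __future__ import annotations

#: Bondi van der Waals radii, A.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "Ne": 1.54,
    "O": 1.52,
    "F": 1.47,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

#: Experimental equilibrium bond lengths of the hydrogen halides, A.
HALIDE_BOND_LENGTHS: dict[str, float] = {
    "F": 0.9169,
    "Cl": 1.2746,
    "Br": 1.4144,
    "I": 1.6092,
}

#: Water monomer experimental equilibrium geometry.
WATER_OH_LENGTH: float = 0.9572  # A
WATER_HOH_ANGLE: float = 104.52  # degrees

#: Grid anchors: the halogen sits at [0, 4] A on the 4 x 8 A^2 grid, the water
#: oxygen at [3, 3(, 3)] A, the centre of its 3 A-wide grids.
HALIDE_GRID_ANCHOR: tuple[float, float, float] = (0.0, 4.0, 0.0)
WATER_GRID_ANCHOR: tuple[float, float, float] = (3.0, 3.0, 3.0)

#: Default probe-grid protocol.
HALIDE_GRID_EXTENT: tuple[float, float] = (4.0, 8.0)  # A
WATER_2D_GRID_EXTENT: tuple[float, float] = (3.0, 3.0)  # A
WATER_3D_GRID_EXTENT: tuple[float, float, float] = (3.0, 3.0, 3.0)  # A
DEFAULT_GRID_SPACING: float = 0.1  # A
DEFAULT_PROBE_ELEMENT: str = "He"

#: Points with model/reference exchange above this are excluded from fits.
DEFAULT_EXCHANGE_THRESHOLD: float = 100.0  # kJ/mol
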