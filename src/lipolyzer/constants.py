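"""Atomic masses and small-molecule constants used for molar-mass arithmetic.

All masses are IUPAC standard atomic weights rounded to 4 decimals and kept
in one place so downstream molar-mass computations are bit-stable.
"""

CARBON = 12.011
HYDROGEN = 1.008
OXYGEN = 15.999

#: H2O, g/mol — lost once per ester bond formed.
WATER = 2 * HYDROGEN + OXYGEN

#: Glycerol C3H8O3, g/mol — the backbone of every acylglycerol.
GLYCEROL = 3 * CARBON + 8 * HYDROGEN + 3 * OXYGEN


def fatty_acid_mass(carbons: int, double_bonds: int) -> float:
    """Molar mass (g/mol) of a straight-chain fatty acid CnH(2n-2d)O2."""
    hydrogens = 2 * carbons - 2 * double_bonds
    return carbons * CARBON + hydrogens * HYDROGEN + 2 * OXYGEN
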