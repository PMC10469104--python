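"""Embedded per-residue physicochemical property scales and pKa values.

Nine scales ship with the package; each maps the 20 canonical residues to a
real value.  The unknown residue ``X`` always takes the arithmetic mean of
the 20 canonical values of a scale, so every valid sequence stays
computable.

Units: ``residue_mass`` in Da (average residue masses, i.e. amino acid
minus water), ``charge_ph7`` in elementary charges, ``side_chain_volume``
in cubic angstroms, the rest are dimensionless index values on their
original published scales.
"""

from __future__ import annotations

from .core import CANONICAL_RESIDUES

# Ionizable-group pKa values (Lehninger): used by the charge/pI model.
PKA_NTERM = 9.69
PKA_CTERM = 2.34
PKA_SIDECHAIN_POSITIVE = {"K": 10.53, "R": 12.48, "H": 6.0}
PKA_SIDECHAIN_NEGATIVE = {"D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07}

WATER_MASS = 18.02  # Da, added back for whole-peptide molecular weight


def _scale(values: dict[str, float]) -> dict[str, float]:
    missing = set(CANONICAL_RESIDUES) - set(values)
    if missing:  # guards the embedded tables themselves
        raise ValueError(f"scale missing residues {sorted(missing)}")
    out = dict(values)
    out["X"] = sum(values[r] for r in CANONICAL_RESIDUES) / 20.0
    return out


#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = _scale({
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
})

#: Eisenberg consensus hydrophobicity.
EISENBERG = _scale({
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
})

#: Nominal side-chain charge at pH 7 (H carries a small positive fraction).
CHARGE_PH7 = _scale({
    "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0,
    "E": -1.0, "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0,
    "M": 0.0, "F": 0.0, "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0,
    "Y": 0.0, "V": 0.0,
})

#: Average residue mass in Da (monomer minus water).
RESIDUE_MASS = _scale({
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "Q": 128.1307, "E": 129.1155, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
})

#: Isoelectric point of the free amino acid (pH units).
RESIDUE_PI = _scale({
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
})

#: Residue volume (Zamyatnin), cubic angstroms.
SIDE_CHAIN_VOLUME = _scale({
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
})

#: Grantham polarity.
POLARITY = _scale({
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
})

#: Average chain flexibility (normalized B-factor scale).
FLEXIBILITY = _scale({
    "A": 0.984, "R": 1.008, "N": 1.048, "D": 1.068, "C": 0.906, "Q": 1.037,
    "E": 1.094, "G": 1.031, "H": 0.950, "I": 0.927, "L": 0.935, "K": 1.102,
    "M": 0.952, "F": 0.915, "P": 1.049, "S": 1.046, "T": 0.997, "W": 0.904,
    "Y": 0.929, "V": 0.931,
})

#: Chou–Fasman alpha-helix propensity.
HELIX_PROPENSITY = _scale({
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
    "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
    "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
    "Y": 0.69, "V": 1.06,
})

PROPERTY_SCALES: dict[str, dict[str, float]] = {
    "kyte_doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG,
    "charge_ph7": CHARGE_PH7,
    "residue_mass": RESIDUE_MASS,
    "residue_pi": RESIDUE_PI,
    "side_chain_volume": SIDE_CHAIN_VOLUME,
    "polarity": POLARITY,
    "flexibility": FLEXIBILITY,
    "helix_propensity": HELIX_PROPENSITY,
}


def get_scale(name: str) -> dict[str, float]:
    """Return an embedded property scale by name.

    Raises ``KeyError`` listing the available scales for unknown names.
    """
    try:
        return PROPERTY_SCALES[name]
    except KeyError:
        raise KeyError(
            f"unknown scale {name!r}; embedded scales: "
            f"{sorted(PROPERTY_SCALES)}"
        ) from None
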