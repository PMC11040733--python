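"""Physical constants, residue tables and van-der-Waals radii.

All internal distances are in Angstrom, angles in radians, energies in the
generic energy unit ``eps`` (mapped to 1 kJ/mol on GROMACS export).
Temperatures are expressed in the reduced unit kappa, related to the thermal
energy through ``kT = KB * T`` with the Boltzmann constant below; this makes
kappa numerically the "Kelvin-shaped" unit a simulation engine sees when the
energy unit is 1 kJ/mol.
"""

# Boltzmann constant in eps / kappa (numerically the gas constant in
# kJ/mol/K, since eps maps to 1 kJ/mol in exported files).
KB = 0.0083144626

#: 2^(1/6): a 12-6 Lennard-Jones potential with minimum at r0 crosses zero
#: at sigma = r0 / SIXTH_ROOT_OF_TWO.
SIXTH_ROOT_OF_TWO = 2.0 ** (1.0 / 6.0)

#: Three-letter -> one-letter codes of the 20 standard amino acids.
STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in STANDARD_AA.items()}

#: Bondi-style van-der-Waals radii (Angstrom). H follows the commonly used
#: 1.10 A revision. Fixed table so contact maps are deterministic; elements
#: outside this table are rejected during structure validation.
VDW_RADII = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


def vdw_radius(element: str) -> float:
    """Van-der-Waals radius of *element* (case-insensitive).

    Raises
    ------
    KeyError
        If the element is not in the fixed internal table.
    """
    key = element.strip().upper()
    try:
        return VDW_RADII[key]
    except KeyError:
        raise KeyError(
            f"no van-der-Waals radius tabulated for element {element!r}; "
            "contact detection requires a known element for every atom"
        ) from None
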