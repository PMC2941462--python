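"""Reference chemistry tables.

Van der Waals radii, standard amino-acid side-chain connectivity, and the
derived table of carbonaceous nonpolar (CH_n) side-chain carbons used for
wrapping counts.
"""

from __future__ import annotations

# Bondi van der Waals radii (Å); used to inflate atoms when building the
# solvent-accessible envelope.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Default probe radius for the solvent-accessible envelope (Å).
PROBE_RADIUS = 1.4

#: Residue names recognized as water when routing HETATM records to solvent.
WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL"}

# Heavy-atom connectivity of standard side chains: for every side-chain
# carbon, the heavy atoms it is covalently bonded to.  Backbone atoms and
# hydrogens are omitted except CA/N where a side-chain carbon bonds to them.
SIDE_CHAIN_CARBON_BONDS: dict[str, dict[str, tuple[str, ...]]] = {
    "ALA": {"CB": ("CA",)},
    "ARG": {
        "CB": ("CA", "CG"),
        "CG": ("CB", "CD"),
        "CD": ("CG", "NE"),
        "CZ": ("NE", "NH1", "NH2"),
    },
    "ASN": {"CB": ("CA", "CG"), "CG": ("CB", "OD1", "ND2")},
    "ASP": {"CB": ("CA", "CG"), "CG": ("CB", "OD1", "OD2")},
    "CYS": {"CB": ("CA", "SG")},
    "GLN": {"CB": ("CA", "CG"), "CG": ("CB", "CD"), "CD": ("CG", "OE1", "NE2")},
    "GLU": {"CB": ("CA", "CG"), "CG": ("CB", "CD"), "CD": ("CG", "OE1", "OE2")},
    "GLY": {},
    "HIS": {
        "CB": ("CA", "CG"),
        "CG": ("CB", "ND1", "CD2"),
        "CD2": ("CG", "NE2"),
        "CE1": ("ND1", "NE2"),
    },
    "ILE": {
        "CB": ("CA", "CG1", "CG2"),
        "CG1": ("CB", "CD1"),
        "CG2": ("CB",),
        "CD1": ("CG1",),
    },
    "LEU": {
        "CB": ("CA", "CG"),
        "CG": ("CB", "CD1", "CD2"),
        "CD1": ("CG",),
        "CD2": ("CG",),
    },
    "LYS": {
        "CB": ("CA", "CG"),
        "CG": ("CB", "CD"),
        "CD": ("CG", "CE"),
        "CE": ("CD", "NZ"),
    },
    "MET": {"CB": ("CA", "CG"), "CG": ("CB", "SD"), "CE": ("SD",)},
    "PHE": {
        "CB": ("CA", "CG"),
        "CG": ("CB", "CD1", "CD2"),
        "CD1": ("CG", "CE1"),
        "CD2": ("CG", "CE2"),
        "CE1": ("CD1", "CZ"),
        "CE2": ("CD2", "CZ"),
        "CZ": ("CE1", "CE2"),
    },
    "PRO": {"CB": ("CA", "CG"), "CG": ("CB", "CD"), "CD": ("CG", "N")},
    "SER": {"CB": ("CA", "OG")},
    "THR": {"CB": ("CA", "OG1", "CG2"), "CG2": ("CB",)},
    "TRP": {
        "CB": ("CA", "CG"),
        "CG": ("CB", "CD1", "CD2"),
        "CD1": ("CG", "NE1"),
        "CD2": ("CG", "CE2", "CE3"),
        "CE2": ("CD2", "NE1", "CZ2"),
        "CE3": ("CD2", "CZ3"),
        "CZ2": ("CE2", "CH2"),
        "CZ3": ("CE3", "CH2"),
        "CH2": ("CZ2", "CZ3"),
    },
    "TYR": {
        "CB": ("CA", "CG"),
        "CG": ("CB", "CD1", "CD2"),
        "CD1": ("CG", "CE1"),
        "CD2": ("CG", "CE2"),
        "CE1": ("CD1", "CZ"),
        "CE2": ("CD2", "CZ"),
        "CZ": ("CE1", "CE2", "OH"),
    },
    "VAL": {"CB": ("CA", "CG1", "CG2"), "CG1": ("CB",), "CG2": ("CB",)},
}

_HETERO_PREFIXES = ("N", "O", "S")


def _bonded_to_heteroatom(neighbors: tuple[str, ...]) -> bool:
    return any(n.startswith(_HETERO_PREFIXES) for n in neighbors)


def nonpolar_carbon_names(
    residue_name: str, include_heteroatom_bonded: bool = False
) -> frozenset[str]:
    """Side-chain carbons of ``residue_name`` that count as CH_n nonpolar groups.

    A side-chain carbon qualifies when none of its covalent heavy-atom
    neighbors is nitrogen, oxygen or sulfur.  ``include_heteroatom_bonded``
    relaxes the rule so every side-chain carbon qualifies (e.g. to count the
    Cβ of Ser/Thr/Cys).  Unknown residue names yield the empty set.
    """
    bonds = SIDE_CHAIN_CARBON_BONDS.get(residue_name)
    if bonds is None:
        return frozenset()
    if include_heteroatom_bonded:
        return frozenset(bonds)
    return frozenset(
        name for name, nbrs in bonds.items() if not _bonded_to_heteroatom(nbrs)
    )


#: Nonpolar-group count per standard residue under the strict rule, for
#: cross-checking classification.
NONPOLAR_GROUP_COUNTS: dict[str, int] = {
    name: len(nonpolar_carbon_names(name)) for name in SIDE_CHAIN_CARBON_BONDS
}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
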