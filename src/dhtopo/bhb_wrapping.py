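"""Backbone hydrogen bonds, wrapping, and dehydron classification.

A backbone hydrogen bond (BHB) is a geometric amide(N-H) -> carbonyl(O=C)
interaction with N-O distance < 3.2 Å and an angle between the N-H and O=C
bond directions in [120°, 180°].  Its wrapping ρ counts the side-chain
carbonaceous CH_n carbons inside the desolvation domain — the union of two
6 Å spheres centered on the α-carbons of the bonded residues.  Bonds with
ρ ≤ 19 (mean 26.6 minus one standard deviation 7.5 over soluble PDB
structures) are under-wrapped: exposed BHBs, also called dehydrons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_model import (
    AtomRecord,
    ProteinStructure,
    Residue,
    StructureError,
)

__all__ = [
    "BackboneHydrogenBond",
    "WrappingResult",
    "MissingHydrogensError",
    "detect_bhbs",
    "compute_wrapping",
    "classify_ebhb",
    "population_threshold",
    "annotate_bonds",
    "bonds_table",
    "DEFAULT_NO_CUTOFF",
    "DEFAULT_ANGLE_RANGE",
    "DEFAULT_DESOLVATION_RADIUS",
    "DEFAULT_EBHB_THRESHOLD",
]

DEFAULT_NO_CUTOFF = 3.2  # Å, donor N to acceptor O
DEFAULT_ANGLE_RANGE = (120.0, 180.0)  # degrees, N-H vs O=C bond directions
DEFAULT_DESOLVATION_RADIUS = 6.0  # Å, per Cα sphere (~three water layers)
DEFAULT_EBHB_THRESHOLD = 19  # wrappers; mean 26.6 - SD 7.5, floored


class MissingHydrogensError(StructureError):
    """Raised when bond detection runs on a structure without amide hydrogens."""


@dataclass
class BackboneHydrogenBond:
    """A donor amide / acceptor carbonyl pair with geometry and wrapping."""

    donor: Residue
    acceptor: Residue
    n_o_distance: float
    a_hb: float
    baricenter: np.ndarray
    rho: int | None = None
    is_ebhb: bool | None = None
    summary_theta: float | None = None
    buried: bool = False

    @property
    def label(self) -> str:
        return f"{self.donor.label}->{self.acceptor.label}"

    @property
    def carbonyl_o(self) -> AtomRecord:
        return self.acceptor.atoms["O"]


@dataclass
class WrappingResult:
    bond: BackboneHydrogenBond
    wrappers: list[AtomRecord] = field(default_factory=list)
    desolvation_radius: float = DEFAULT_DESOLVATION_RADIUS


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def detect_bhbs(
    structure: ProteinStructure,
    no_cutoff: float = DEFAULT_NO_CUTOFF,
    angle_range: tuple[float, float] = DEFAULT_ANGLE_RANGE,
    min_seq_separation: int = 2,
    include_interchain: bool = False,
) -> list[BackboneHydrogenBond]:
    """Detect every backbone hydrogen bond in ``structure``.

    Pairs a donor amide (N-H of residue i) with an acceptor carbonyl
    (C=O of residue j) when the donor-N to acceptor-O distance is below
    ``no_cutoff`` and the angle between the N->H and O->C bond directions
    (180° when collinear) lies in ``angle_range``.  Same-chain pairs with
    sequence separation |i - j| < ``min_seq_separation`` are excluded as
    covalent-geometry artifacts; a donor may bond two acceptors
    (bifurcation) and each pair is listed once.
    """
    if not structure.hydrogens_placed and not any(
        "H" in r.atoms for r in structure.residues
    ):
        raise MissingHydrogensError(
            "no amide hydrogens present; run place_amide_hydrogens() first"
        )
    donors = [
        r
        for r in structure.residues
        if r.is_complete and "H" in r.atoms
    ]
    acceptors = [r for r in structure.residues if r.is_complete]
    if not donors or not acceptors:
        return []

    acc_o = np.array([r.atoms["O"].position for r in acceptors])
    lo, hi = angle_range
    bonds: list[BackboneHydrogenBond] = []
    for don in donors:
        n_pos = don.atoms["N"].position
        h_pos = don.atoms["H"].position
        d = np.linalg.norm(acc_o - n_pos, axis=1)
        for j in np.nonzero(d < no_cutoff)[0]:
            acc = acceptors[j]
            if acc.chain_id == don.chain_id:
                if abs(acc.number - don.number) < min_seq_separation:
                    continue
            elif not include_interchain:
                continue
            # a donor N covalently bonded to the acceptor C is a peptide artifact
            if np.linalg.norm(n_pos - acc.atoms["C"].position) < 1.8:
                continue
            o_pos = acc.atoms["O"].position
            c_pos = acc.atoms["C"].position
            a_hb = _angle_deg(h_pos - n_pos, o_pos - c_pos)
            if lo <= a_hb <= hi:
                bonds.append(
                    BackboneHydrogenBond(
                        donor=don,
                        acceptor=acc,
                        n_o_distance=float(d[j]),
                        a_hb=a_hb,
                        baricenter=0.5 * (n_pos + o_pos),
                    )
                )
    bonds.sort(key=lambda b: (b.donor.chain_id, b.donor.seq_pos, b.acceptor.chain_id, b.acceptor.seq_pos))
    return bonds


def compute_wrapping(
    bond: BackboneHydrogenBond,
    structure: ProteinStructure,
    desolvation_radius: float = DEFAULT_DESOLVATION_RADIUS,
) -> WrappingResult:
    """Count CH_n wrappers inside the bond's two-sphere desolvation domain.

    ρ is the number of classified nonpolar side-chain carbons whose center
    lies within ``desolvation_radius`` of either paired α-carbon; a carbon
    in both spheres counts once.  Sets ``bond.rho``.
    """
    if desolvation_radius <= 0:
        raise ValueError("desolvation_radius must be positive")
    if not structure.nonpolar_classified:
        raise StructureError(
            "nonpolar groups not classified; run classify_nonpolar_groups() first"
        )
    ca_d = bond.donor.atoms["CA"].position
    ca_a = bond.acceptor.atoms["CA"].position
    wrappers = []
    for atom in structure.nonpolar_groups:
        p = atom.position
        if (
            np.linalg.norm(p - ca_d) <= desolvation_radius
            or np.linalg.norm(p - ca_a) <= desolvation_radius
        ):
            wrappers.append(atom)
    bond.rho = len(wrappers)
    return WrappingResult(bond=bond, wrappers=wrappers, desolvation_radius=desolvation_radius)


def classify_ebhb(
    bond: BackboneHydrogenBond, threshold: int = DEFAULT_EBHB_THRESHOLD
) -> bool:
    """True when the bond is under-wrapped (ρ ≤ threshold): a dehydron."""
    if bond.rho is None:
        raise StructureError(f"wrapping not computed for {bond.label}")
    bond.is_ebhb = bond.rho <= threshold
    return bond.is_ebhb


def population_threshold(rhos: "list[int] | np.ndarray") -> int:
    """EBHB cutoff recomputed from a bond population: floor(mean - 1 SD)."""
    arr = np.asarray(rhos, dtype=float)
    if arr.size == 0:
        raise ValueError("empty ρ population")
    return int(math.floor(arr.mean() - arr.std(ddof=0)))


def annotate_bonds(
    structure: ProteinStructure,
    desolvation_radius: float = DEFAULT_DESOLVATION_RADIUS,
    threshold: int | None = DEFAULT_EBHB_THRESHOLD,
    **detect_kwargs,
) -> list[BackboneHydrogenBond]:
    """Detect bonds, compute ρ for each, and flag dehydrons.

    ``threshold=None`` recomputes the cutoff from this structure's own ρ
    population (floor of mean minus one SD).
    """
    bonds = detect_bhbs(structure, **detect_kwargs)
    for bond in bonds:
        compute_wrapping(bond, structure, desolvation_radius)
    if bonds:
        thr = threshold if threshold is not None else population_threshold(
            [b.rho for b in bonds]
        )
        for bond in bonds:
            classify_ebhb(bond, thr)
    return bonds


def bonds_table(bonds: list[BackboneHydrogenBond]) -> pd.DataFrame:
    """Per-bond output table (one row per bond, report-ready)."""
    rows = []
    for b in bonds:
        rows.append(
            {
                "donor": b.donor.label,
                "acceptor": b.acceptor.label,
                "chain": b.donor.chain_id,
                "n_o_distance": round(b.n_o_distance, 3),
                "a_hb": round(b.a_hb, 2),
                "rho": b.rho,
                "is_ebhb": b.is_ebhb,
                "baricenter_x": round(float(b.baricenter[0]), 3),
                "baricenter_y": round(float(b.baricenter[1]), 3),
                "baricenter_z": round(float(b.baricenter[2]), 3),
                "summary_theta": None if b.summary_theta is None else round(b.summary_theta, 3),
                "buried": b.buried,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "donor", "acceptor", "chain", "n_o_distance", "a_hb", "rho",
            "is_ebhb", "baricenter_x", "baricenter_y", "baricenter_z",
            "summary_theta", "buried",
        ],
    )
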