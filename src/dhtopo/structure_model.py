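"""Protein structure input, normalization, and solvent-frame handling.

Reads PDB files into a lightweight coordinate model, resolves alternate
locations, places amide hydrogens with ideal trans-peptide geometry,
classifies side-chain carbonaceous nonpolar (CH_n) groups, and parses
explicit-solvent configurations from multi-model PDB or XYZ frame files.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .data import (
    DEFAULT_VDW,
    VDW_RADII,
    WATER_RESNAMES,
    nonpolar_carbon_names,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "ProteinStructure",
    "SolventFrame",
    "StructureError",
    "ParseError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "structure_to_pdb_string",
    "read_solvent_frames",
    "write_xyz_frames",
    "place_amide_hydrogens",
    "classify_nonpolar_groups",
]


class StructureError(ValueError):
    """Base error for structure handling."""


class ParseError(StructureError):
    """Raised when an input file cannot be parsed."""


class EmptyStructureError(StructureError):
    """Raised when a file contains no protein atoms."""


@dataclass
class AtomRecord:
    """One atom with normalized chemistry metadata.

    ``residue_index`` is the author (PDB) residue number; sequence ordinals
    live on :class:`Residue`.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.name} {self.residue_name}{self.residue_index}: "
                "position must be a finite 3-vector"
            )

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_VDW)


@dataclass
class Residue:
    """A residue: author number plus 0-based ordinal within its chain."""

    chain_id: str
    number: int
    name: str
    seq_pos: int
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    def get(self, atom_name: str) -> AtomRecord | None:
        return self.atoms.get(atom_name)

    @property
    def is_complete(self) -> bool:
        """True when the residue has the full N, CA, C, O backbone."""
        return all(n in self.atoms for n in ("N", "CA", "C", "O"))

    @property
    def label(self) -> str:
        return f"{self.name}{self.number}:{self.chain_id}"


@dataclass
class SolventFrame:
    """Water coordinates for one solvent configuration.

    ``oxygens`` is (n, 3); ``hydrogens`` is (n, 2, 3) with NaN rows for
    absent hydrogens, or None when the frame carries no hydrogens at all.
    ``expected_g`` is generator metadata (intended coordination per water)
    and is ignored by all analysis code.
    """

    frame_index: int
    oxygens: np.ndarray
    hydrogens: np.ndarray | None = None
    expected_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.oxygens = np.asarray(self.oxygens, dtype=float).reshape(-1, 3)
        if self.hydrogens is not None:
            self.hydrogens = np.asarray(self.hydrogens, dtype=float).reshape(-1, 2, 3)
            if len(self.hydrogens) != len(self.oxygens):
                raise StructureError("hydrogens array must match oxygens length")
            d = np.linalg.norm(self.hydrogens - self.oxygens[:, None, :], axis=-1)
            d = d[np.isfinite(d)]
            if d.size and (np.any(d <= 0.5) or np.any(d >= 1.3)):
                raise StructureError("O-H distance outside (0.5, 1.3) Å")

    @property
    def n_waters(self) -> int:
        return len(self.oxygens)

    @property
    def has_hydrogens(self) -> bool:
        return self.hydrogens is not None and bool(
            np.any(np.isfinite(self.hydrogens))
        )

    @property
    def waters(self) -> list[tuple[np.ndarray, np.ndarray | None, np.ndarray | None]]:
        out = []
        for i, o in enumerate(self.oxygens):
            h1 = h2 = None
            if self.hydrogens is not None:
                cand = self.hydrogens[i]
                h1 = cand[0] if np.all(np.isfinite(cand[0])) else None
                h2 = cand[1] if np.all(np.isfinite(cand[1])) else None
            out.append((o, h1, h2))
        return out


@dataclass
class ProteinStructure:
    """Normalized protein coordinate model: the substrate of every stage."""

    residues: list[Residue] = field(default_factory=list)
    nonpolar_groups: list[AtomRecord] = field(default_factory=list)
    solvent: SolventFrame | None = None
    hydrogens_placed: bool = False
    nonpolar_classified: bool = False

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms.values()]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def backbone_index(self, residue: Residue) -> dict[str, AtomRecord | None]:
        """Backbone atoms (N, H amide, CA, C, O) of ``residue``."""
        return {
            "N": residue.get("N"),
            "H": residue.get("H"),
            "CA": residue.get("CA"),
            "C": residue.get("C"),
            "O": residue.get("O"),
        }

    def heavy_coords(self) -> np.ndarray:
        pos = [a.position for a in self.atoms if a.element.upper() != "H"]
        return np.array(pos, dtype=float).reshape(-1, 3)

    def translated(self, shift: np.ndarray) -> "ProteinStructure":
        return self.transformed(np.eye(3), np.asarray(shift, dtype=float))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Rigid-body copy: x -> R x + t applied to every atom."""
        import copy

        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        new = copy.deepcopy(self)  # deepcopy preserves atom aliasing in nonpolar_groups
        for atom in new.atoms:
            atom.position = rot @ atom.position + tr
        if new.solvent is not None:
            new.solvent.oxygens = new.solvent.oxygens @ rot.T + tr
            if new.solvent.hydrogens is not None:
                new.solvent.hydrogens = new.solvent.hydrogens @ rot.T + tr
        return new


# ---------------------------------------------------------------------------
# PDB input


def _element_of(atom) -> str:
    el = (atom.element or "").strip()
    if not el:
        name = atom.get_name().strip()
        el = next((c for c in name if c.isalpha()), "C")
    return el.upper()


def read_structure(
    path: str | Path | io.StringIO, model_index: int = 0
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    One model is used (``model_index``, default the first).  Alternate
    locations are resolved to the highest occupancy (tie: lowest altloc
    identifier).  HETATM records are discarded except waters, which are
    collected into ``structure.solvent`` as frame 0.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            if isinstance(path, io.StringIO):
                bio = parser.get_structure("s", path)
            else:
                bio = parser.get_structure("s", str(path))
    except Exception as exc:  # Bio.PDB raises heterogeneous exceptions
        raise ParseError(f"cannot parse PDB input: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise EmptyStructureError("no MODEL/ATOM content in file")
    if model_index >= len(models):
        raise StructureError(
            f"model_index {model_index} out of range ({len(models)} models)"
        )
    model = models[model_index]

    structure = ProteinStructure()
    water_o: list[np.ndarray] = []
    water_h: list[list[np.ndarray]] = []
    serial = 0
    for chain in model:
        seq_pos = 0
        for bio_res in chain:
            hetflag, resseq, _icode = bio_res.get_id()
            resname = bio_res.get_resname().strip()
            if resname in WATER_RESNAMES:
                o, hs = None, []
                for atom in bio_res.get_unpacked_list():
                    el = _element_of(atom)
                    if el == "O":
                        o = np.array(atom.get_coord(), dtype=float)
                    elif el == "H":
                        hs.append(np.array(atom.get_coord(), dtype=float))
                if o is not None:
                    water_o.append(o)
                    water_h.append(hs[:2])
                continue
            if hetflag.strip():
                continue  # non-water HETATM discarded
            residue = Residue(
                chain_id=chain.id, number=resseq, name=resname, seq_pos=seq_pos
            )
            # altloc resolution: highest occupancy, tie -> lowest altloc id
            best: dict[str, tuple[float, str, AtomRecord]] = {}
            for atom in bio_res.get_unpacked_list():
                serial += 1
                name = atom.get_name().strip()
                rec = AtomRecord(
                    serial=serial,
                    name=name,
                    element=_element_of(atom),
                    residue_name=resname,
                    residue_index=resseq,
                    chain_id=chain.id,
                    position=np.array(atom.get_coord(), dtype=float),
                    occupancy=float(atom.get_occupancy() or 1.0),
                    altloc=(atom.get_altloc() or "").strip(),
                )
                key = name
                incumbent = best.get(key)
                cand = (-rec.occupancy, rec.altloc or "~")
                if incumbent is None or cand < (-incumbent[0], incumbent[1] or "~"):
                    best[key] = (rec.occupancy, rec.altloc, rec)
            for _, _, rec in best.values():
                rec.altloc = ""
                residue.atoms[rec.name] = rec
            if residue.atoms:
                if not residue.is_complete:
                    logger.warning(
                        "residue %s incomplete backbone; excluded from bond detection",
                        residue.label,
                    )
                structure.residues.append(residue)
                seq_pos += 1

    if not structure.residues:
        raise EmptyStructureError("no protein residues found")
    if water_o:
        n = len(water_o)
        h = np.full((n, 2, 3), np.nan)
        for i, hs in enumerate(water_h):
            for j, hj in enumerate(hs):
                h[i, j] = hj
        structure.solvent = SolventFrame(
            frame_index=0,
            oxygens=np.array(water_o),
            hydrogens=h if np.any(np.isfinite(h)) else None,
        )
    return structure


# ---------------------------------------------------------------------------
# PDB output


def _format_atom_line(serial: int, atom: AtomRecord) -> str:
    name = atom.name
    # PDB column convention: element symbols of one letter start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    x, y, z = atom.position
    return (
        f"ATOM  {serial:5d} {name:<4s} {atom.residue_name:<3s} "
        f"{atom.chain_id:1s}{atom.residue_index:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def structure_to_pdb_string(structure: ProteinStructure) -> str:
    lines = []
    serial = 0
    for res in structure.residues:
        for atom in res.atoms.values():
            serial += 1
            lines.append(_format_atom_line(serial, atom))
    if structure.solvent is not None:
        for i, (o, h1, h2) in enumerate(structure.solvent.waters):
            for name, el, pos in (("O", "O", o), ("H1", "H", h1), ("H2", "H", h2)):
                if pos is None:
                    continue
                serial += 1
                x, y, z = pos
                lines.append(
                    f"HETATM{serial:5d}  {name:<3s} HOH W{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {el:>2s}"
                )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(structure: ProteinStructure, path: str | Path) -> None:
    Path(path).write_text(structure_to_pdb_string(structure))


# ---------------------------------------------------------------------------
# Solvent frames


def read_solvent_frames(path: str | Path) -> list[SolventFrame]:
    """Read explicit-solvent frames from multi-model PDB or XYZ.

    XYZ frames follow the layout: one comment line, then one ``O x y z``
    line optionally followed by up to two ``H x y z`` lines per molecule.
    Format is chosen by sniffing the first non-blank line.
    """
    text = Path(path).read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.startswith(("ATOM", "HETATM", "MODEL", "REMARK", "HEADER", "CRYST")):
        return _read_pdb_frames(text)
    return _read_xyz_frames(text)


def _read_pdb_frames(text: str) -> list[SolventFrame]:
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio = parser.get_structure("frames", io.StringIO(text))
    frames = []
    for fi, model in enumerate(bio.get_models()):
        o_list, h_list = [], []
        for chain in model:
            for res in chain:
                if res.get_resname().strip() not in WATER_RESNAMES:
                    continue
                o, hs = None, []
                for atom in res.get_unpacked_list():
                    if _element_of(atom) == "O":
                        o = np.array(atom.get_coord(), dtype=float)
                    elif _element_of(atom) == "H":
                        hs.append(np.array(atom.get_coord(), dtype=float))
                if o is not None:
                    o_list.append(o)
                    h_list.append(hs[:2])
        if not o_list:
            continue
        n = len(o_list)
        h = np.full((n, 2, 3), np.nan)
        for i, hs in enumerate(h_list):
            for j, hj in enumerate(hs):
                h[i, j] = hj
        frames.append(
            SolventFrame(
                frame_index=fi,
                oxygens=np.array(o_list),
                hydrogens=h if np.any(np.isfinite(h)) else None,
            )
        )
    if not frames:
        raise ParseError("no water molecules found in PDB frame file")
    return frames


def _read_xyz_frames(text: str) -> list[SolventFrame]:
    lines = text.splitlines()
    frames: list[SolventFrame] = []
    i = 0
    fi = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        # comment line opens each frame
        i += 1
        o_list: list[np.ndarray] = []
        h_list: list[list[np.ndarray]] = []
        while i < len(lines) and lines[i].strip():
            parts = lines[i].split()
            if len(parts) != 4:
                raise ParseError(f"XYZ frame line {i + 1}: expected 'SYM x y z'")
            sym = parts[0].upper()
            try:
                pos = np.array([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"XYZ frame line {i + 1}: {exc}") from exc
            if sym == "O":
                o_list.append(pos)
                h_list.append([])
            elif sym == "H":
                if not o_list:
                    raise ParseError(f"XYZ frame line {i + 1}: H before any O")
                h_list[-1].append(pos)
            else:
                raise ParseError(f"XYZ frame line {i + 1}: unknown symbol {sym!r}")
            i += 1
        if o_list:
            n = len(o_list)
            h = np.full((n, 2, 3), np.nan)
            for k, hs in enumerate(h_list):
                for j, hj in enumerate(hs[:2]):
                    h[k, j] = hj
            frames.append(
                SolventFrame(
                    frame_index=fi,
                    oxygens=np.array(o_list),
                    hydrogens=h if np.any(np.isfinite(h)) else None,
                )
            )
            fi += 1
    if not frames:
        raise ParseError("no frames found in XYZ input")
    return frames


def write_xyz_frames(frames: Sequence[SolventFrame], path: str | Path) -> None:
    out = []
    for fr in frames:
        out.append(f"# frame {fr.frame_index}  n_waters {fr.n_waters}")
        for o, h1, h2 in fr.waters:
            out.append(f"O {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}")
            for h in (h1, h2):
                if h is not None:
                    out.append(f"H {h[0]:.4f} {h[1]:.4f} {h[2]:.4f}")
        out.append("")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Normalization


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise StructureError("degenerate geometry: zero-length bond vector")
    return v / n


def place_amide_hydrogens(
    structure: ProteinStructure, nh_length: float = 1.0
) -> ProteinStructure:
    """Add missing backbone amide hydrogens in ideal trans-peptide geometry.

    The hydrogen is placed ``nh_length`` Å from N, in the plane of
    C(prev)-N-CA, opposite the bisector of the C(prev)->N and CA->N bond
    directions.  Proline and chain N-termini get no amide hydrogen;
    pre-existing hydrogens are kept unchanged.  Returns the same structure
    (mutated in place) for chaining.
    """
    for chain_residues in structure.chains().values():
        prev: Residue | None = None
        for res in chain_residues:
            try:
                if res.name == "PRO" or "H" in res.atoms or not res.is_complete:
                    continue
                if prev is None or "C" not in prev.atoms:
                    logger.info("no preceding residue for %s; amide H omitted", res.label)
                    continue
                n_pos = res.atoms["N"].position
                c_prev = prev.atoms["C"].position
                # skip across chain breaks
                if np.linalg.norm(n_pos - c_prev) > 2.0:
                    logger.info("chain break before %s; amide H omitted", res.label)
                    continue
                ca_pos = res.atoms["CA"].position
                bisector = _unit(_unit(c_prev - n_pos) + _unit(ca_pos - n_pos))
                h_pos = n_pos - nh_length * bisector
                res.atoms["H"] = AtomRecord(
                    serial=0,
                    name="H",
                    element="H",
                    residue_name=res.name,
                    residue_index=res.number,
                    chain_id=res.chain_id,
                    position=h_pos,
                )
            finally:
                prev = res
    structure.hydrogens_placed = True
    return structure


def classify_nonpolar_groups(
    structure: ProteinStructure, include_heteroatom_bonded: bool = False
) -> ProteinStructure:
    """Populate ``structure.nonpolar_groups`` with CH_n side-chain carbons.

    A side-chain carbon qualifies when its covalent neighbors (from the
    bundled amino-acid topology table) include no N, O or S.  Nonstandard
    residues contribute nothing and are logged.
    """
    groups: list[AtomRecord] = []
    from .data import SIDE_CHAIN_CARBON_BONDS

    nonstandard: dict[str, int] = {}
    for res in structure.residues:
        if res.name not in SIDE_CHAIN_CARBON_BONDS:
            nonstandard[res.name] = nonstandard.get(res.name, 0) + 1
            continue
        names = nonpolar_carbon_names(res.name, include_heteroatom_bonded)
        for name in sorted(names):
            atom = res.get(name)
            if atom is not None:
                groups.append(atom)
    for resname, count in nonstandard.items():
        logger.warning(
            "nonstandard residue %s (%d occurrences): no nonpolar groups", resname, count
        )
    structure.nonpolar_groups = groups
    structure.nonpolar_classified = True
    return structure
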