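"""Chain model: parse a PDB/mmCIF file into residues of heavy atoms with radii.

The alignment method needs only one chain at a time, heavy atoms only, one
conformer per atom, and a dense 0-based residue index; this module produces
exactly that and nothing more.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import gemmi
import numpy as np

from .config import DEFAULT_RADIUS, VDW_RADII

logger = logging.getLogger(__name__)

#: The 20 standard amino acids.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Common modified residues mapped to their standard parent; anything not
#: listed here and not standard is dropped with a warning.
RESIDUE_ALIASES = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "SEP": "SER", "TPO": "THR",
    "PTR": "TYR", "CSO": "CYS", "HYP": "PRO", "MLY": "LYS", "M3L": "LYS",
    "CME": "CYS", "KCX": "LYS", "LLP": "LYS",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclasses.dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray          # (3,) Å
    radius: float              # van der Waals radius, Å
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")
        if self.radius <= 0:
            raise ValueError(f"non-positive radius for atom {self.name}")


@dataclasses.dataclass
class ResidueRecord:
    seq_index: int             # 0-based dense position in the chain
    residue_name: str          # 3-letter code (after alias mapping)
    atoms: list[AtomRecord]
    author_id: str = ""        # original PDB number + insertion code

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.residue_name, "X")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])


@dataclasses.dataclass
class ChainStructure:
    chain_id: str
    residues: list[ResidueRecord]
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates, NaN rows where a residue lacks a CA atom."""
        out = np.full((len(self.residues), 3), np.nan)
        for k, res in enumerate(self.residues):
            ca = res.atom("CA")
            if ca is not None:
                out[k] = ca.coord
        return out

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


def _element_of(atom_name: str, element: str) -> str:
    el = element.strip().capitalize()
    if el:
        return el
    # fall back to the first alphabetic character of the atom name
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def assign_radii(structure: ChainStructure,
                 radius_table: dict[str, float] | None = None,
                 default: float = DEFAULT_RADIUS) -> ChainStructure:
    """Assign van der Waals radii in place (and return the structure).

    Unknown elements get ``default`` and a logged warning.
    """
    table = VDW_RADII if radius_table is None else radius_table
    warned: set[str] = set()
    for res in structure.residues:
        for atom in res.atoms:
            el = atom.element
            if el in table:
                atom.radius = table[el]
            else:
                if el not in warned:
                    logger.warning(
                        "element %r not in radius table; using default %.2f Å",
                        el, default)
                    warned.add(el)
                atom.radius = default
    return structure


def read_pdb_chain(path: str | Path, chain_id: str,
                   radius_table: dict[str, float] | None = None) -> ChainStructure:
    """Read one chain of a PDB or mmCIF file into a :class:`ChainStructure`.

    Keeps heavy atoms of standard amino acids only (modified residues in
    :data:`RESIDUE_ALIASES` are renamed to their parent); hydrogens, waters
    and ligands are dropped.  For altLoc duplicates the highest-occupancy
    conformer wins (ties: first in file).  Only the first model of an NMR
    ensemble is used.  Residues are re-indexed densely 0..N-1 in file order.

    Raises
    ------
    ValueError
        If the chain is absent (the message lists the available chains), the
        chain has no standard residues, or an atom name is still duplicated
        after altLoc resolution.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model) or "(none)"
        raise ValueError(
            f"{path}: chain {chain_id!r} not found; available chains: {available}")

    residues: list[ResidueRecord] = []
    for res in chain:
        name = res.name.strip().upper()
        if name in RESIDUE_ALIASES:
            name = RESIDUE_ALIASES[name]
        if name not in STANDARD_RESIDUES:
            if res.is_water() or res.het_flag == "H":
                continue
            logger.warning("dropping non-standard residue %s %s", res.name,
                           str(res.seqid))
            continue
        # altLoc resolution: highest occupancy, first-in-file on ties
        best: dict[str, gemmi.Atom] = {}
        altlocs: dict[str, bool] = {}
        order: list[str] = []
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            aname = atom.name.strip()
            has_alt = atom.altloc not in ("", " ", "\x00")
            if aname not in best:
                best[aname] = atom
                altlocs[aname] = has_alt
                order.append(aname)
            elif has_alt and altlocs[aname]:
                if atom.occ > best[aname].occ:
                    best[aname] = atom
            else:
                raise ValueError(
                    f"{path}: residue {name} {res.seqid} has atom {aname!r} "
                    "assigned to multiple coordinates")
        if not best:
            continue
        atoms = []
        for aname in order:
            atom = best[aname]
            atoms.append(AtomRecord(
                name=aname,
                element=_element_of(aname, atom.element.name),
                coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                radius=DEFAULT_RADIUS,
                occupancy=atom.occ,
            ))
        author_id = f"{res.seqid.num}{res.seqid.icode}".strip()
        residues.append(ResidueRecord(
            seq_index=len(residues), residue_name=name, atoms=atoms,
            author_id=author_id))

    if not residues:
        raise ValueError(
            f"{path}: chain {chain_id!r} contains no standard amino-acid residues")
    structure = ChainStructure(chain_id=chain_id, residues=residues,
                               source=str(path))
    return assign_radii(structure, radius_table)


def write_pdb(structure: ChainStructure, path: str | Path) -> None:
    """Write a minimal but valid single-chain PDB file.

    Emits fixed-width ATOM records with occupancy 1.00 and B-factor 0.00 so
    fixtures round-trip through the reader and open in external viewers.
    """
    lines = []
    serial = 1
    for res in structure.residues:
        resseq = res.author_id if res.author_id else str(res.seq_index + 1)
        try:
            num = int(resseq)
            icode = " "
        except ValueError:
            num = int(resseq[:-1])
            icode = resseq[-1]
        for atom in res.atoms:
            name = atom.name
            # PDB column convention: 1-letter elements start in column 14
            field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {field}{'':1s}{res.residue_name:>3s} "
                f"{structure.chain_id:1s}{num:4d}{icode}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
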