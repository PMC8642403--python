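"""Two-chain protein complexes: PDB I/O, interface detection, atomic contacts.

A :class:`Complex` is an ordered list of heavy (or all) atoms belonging to
exactly two chains.  Interface residues are those with any atom within a
distance cutoff (default 5.5 A) of any atom of the partner chain; the same
machinery also exposes the raw cross-chain atom contact pairs used by the
energy features and by FNAT.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Complex",
    "InterfaceSelection",
    "StructureError",
    "PDBParseError",
    "PDBFormatError",
    "parse_pdb",
    "write_pdb",
    "interface_residues",
    "atomic_contact_pairs",
    "VDW_RADII",
    "DEFAULT_VDW_RADIUS",
    "DEFAULT_INTERFACE_CUTOFF",
]

#: van der Waals radii (A) for the heavy elements of protein chemistry.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW_RADIUS = 1.70
DEFAULT_INTERFACE_CUTOFF = 5.5

# Residue identifiers are plain ints, or "52A"-style strings when an
# insertion code is present.
ResidueNumber = Union[int, str]


class StructureError(ValueError):
    """A structure violates a contract (chain count, empty chain, ...)."""


class PDBParseError(StructureError):
    """An ATOM record could not be parsed; the message names the line."""


class PDBFormatError(StructureError):
    """A Complex cannot be written within PDB fixed-column widths."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    chain_id: str
    residue_number: ResidueNumber
    residue_name: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if not all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.serial} ({self.name}) has non-finite coordinates"
            )

    @property
    def residue_id(self) -> tuple[str, ResidueNumber]:
        return (self.chain_id, self.residue_number)

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element, DEFAULT_VDW_RADIUS)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Complex:
    """An ordered two-chain atomic structure."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self):
        chains = []
        for a in self.atoms:
            if a.chain_id not in chains:
                chains.append(a.chain_id)
        if len(chains) != 2:
            raise StructureError(
                f"complex {self.source_id!r} must have exactly two chains, "
                f"found {len(chains)}: {chains}"
            )
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError(f"complex {self.source_id!r} has duplicate atom serials")
        self.chain_ids: tuple[str, str] = (chains[0], chains[1])

    @cached_property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @cached_property
    def chain_mask(self) -> np.ndarray:
        """True for atoms of the first chain (file order)."""
        return np.array([a.chain_id == self.chain_ids[0] for a in self.atoms])

    def chain_atom_indices(self, chain_id: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.chain_id == chain_id],
                        dtype=int)

    def residues(self, chain_id: str | None = None) -> list[tuple[str, ResidueNumber]]:
        """Residue identifiers in atom order (unique, order of first atom)."""
        seen: dict[tuple[str, ResidueNumber], None] = {}
        for a in self.atoms:
            if chain_id is None or a.chain_id == chain_id:
                seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_name_of(self, residue_id: tuple[str, ResidueNumber]) -> str:
        for a in self.atoms:
            if a.residue_id == residue_id:
                return a.residue_name
        raise KeyError(residue_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    center: np.ndarray | None = None) -> "Complex":
        """Return a copy with ``x -> R (x - c) + c + t`` applied to every atom."""
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        new_xyz = (self.coords - c) @ np.asarray(rotation).T + c + np.asarray(translation)
        atoms = [
            Atom(a.serial, a.name, a.element, a.chain_id, a.residue_number,
                 a.residue_name, tuple(p))
            for a, p in zip(self.atoms, new_xyz)
        ]
        return Complex(atoms, source_id=self.source_id)

    @property
    def receptor_chain(self) -> str:
        """Chain with more residues; tie broken by lexicographic chain id."""
        a, b = self.chain_ids
        na, nb = len(self.residues(a)), len(self.residues(b))
        if na != nb:
            return a if na > nb else b
        return min(a, b)

    @property
    def ligand_chain(self) -> str:
        a, b = self.chain_ids
        return b if self.receptor_chain == a else a


@dataclass
class InterfaceSelection:
    cutoff: float
    residues_by_chain: dict[str, set]
    contact_atom_pairs: set[tuple[int, int]]

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.residues_by_chain.values())

    def __bool__(self) -> bool:
        return bool(self.contact_atom_pairs)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    """Element from an atom name when the element column is blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def parse_pdb(text: str, source_id: str = "", include_hetatm: bool = False) -> Complex:
    """Parse PDB-format text into a two-chain :class:`Complex`.

    HETATM records (waters, ligands) are ignored by default.  Only the first
    MODEL of a multi-model file is kept, and only altloc ' ' or 'A' atoms.
    Insertion codes are appended to the residue number as a composite
    identifier (e.g. ``"52A"``).
    """
    from biotite.structure.io.pdb import PDBFile

    # pre-validate coordinate fields so errors can name the offending line
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                int(line[6:11])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError):
                raise PDBParseError(f"unparseable ATOM record at line {lineno}: {line!r}")

    try:
        pdb = PDBFile.read(io.StringIO(text))
        arr = pdb.get_structure(model=1, altloc="first", extra_fields=["atom_id"])
    except Exception as exc:  # biotite's own failure modes
        raise PDBParseError(f"could not parse PDB text: {exc}") from exc

    keep = np.ones(arr.array_length(), dtype=bool)
    if not include_hetatm:
        keep &= ~arr.hetero
    arr = arr[keep]
    if arr.array_length() == 0:
        raise StructureError("no ATOM records found")

    atoms = []
    for i in range(arr.array_length()):
        element = arr.element[i].strip().upper() or _infer_element(arr.atom_name[i])
        icode = arr.ins_code[i].strip()
        resnum: ResidueNumber = int(arr.res_id[i])
        if icode:
            resnum = f"{resnum}{icode}"
        atoms.append(Atom(
            serial=int(arr.atom_id[i]),
            name=arr.atom_name[i].strip(),
            element=element,
            chain_id=arr.chain_id[i].strip(),
            residue_number=resnum,
            residue_name=arr.res_name[i].strip(),
            position=tuple(float(x) for x in arr.coord[i]),
        ))
    return Complex(atoms, source_id=source_id)


def _split_residue_number(resnum: ResidueNumber) -> tuple[int, str]:
    if isinstance(resnum, int):
        return resnum, ""
    s = str(resnum)
    digits = len(s)
    for i, ch in enumerate(s):
        if not (ch.isdigit() or (i == 0 and ch == "-")):
            digits = i
            break
    return int(s[:digits]), s[digits:]


def write_pdb(complex: Complex) -> str:
    """Serialize a Complex as fixed-column ATOM records (3-decimal coords)."""
    lines = []
    prev_chain = None
    for a in complex.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        if len(a.residue_name) > 3 or len(a.name) > 4 or len(a.chain_id) != 1:
            raise PDBFormatError(
                f"atom {a.serial}: name/residue/chain exceeds PDB column widths"
            )
        num, icode = _split_residue_number(a.residue_number)
        if not (-999 <= num <= 9999) or len(icode) > 1:
            raise PDBFormatError(f"residue number {a.residue_number!r} does not fit")
        x, y, z = a.position
        if any(abs(v) >= 10000 for v in (x, y, z)):
            raise PDBFormatError(f"atom {a.serial}: coordinate exceeds PDB columns")
        # column-76 element right-justified in cols 77-78
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:>5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id}{num:>4d}{icode:<1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Interface detection
# ---------------------------------------------------------------------------

def atomic_contact_pairs(complex: Complex, cutoff: float) -> set[tuple[int, int]]:
    """All cross-chain atom index pairs with Euclidean distance <= cutoff.

    Indices refer to positions in ``complex.atoms``; each pair is listed once
    as ``(i, j)`` with ``i`` on the first chain and ``j`` on the second.
    """
    if cutoff <= 0 and cutoff != 0.0:
        raise ValueError("cutoff must be positive")
    mask = complex.chain_mask
    idx_a = np.flatnonzero(mask)
    idx_b = np.flatnonzero(~mask)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise StructureError("both chains must contain atoms")
    xyz = complex.coords
    tree_b = cKDTree(xyz[idx_b])
    pairs: set[tuple[int, int]] = set()
    neighbours = tree_b.query_ball_point(xyz[idx_a], r=cutoff)
    for ia, nbrs in zip(idx_a, neighbours):
        for jb in nbrs:
            pairs.add((int(ia), int(idx_b[jb])))
    return pairs


def interface_residues(complex: Complex,
                       cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> InterfaceSelection:
    """Residues with any atom within ``cutoff`` of any atom of the other chain.

    The distance test is inclusive (<= cutoff).  The selection is exactly the
    residue projection of :func:`atomic_contact_pairs` at the same cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pairs = atomic_contact_pairs(complex, cutoff)
    residues: dict[str, set] = {c: set() for c in complex.chain_ids}
    for i, j in pairs:
        ai, aj = complex.atoms[i], complex.atoms[j]
        residues[ai.chain_id].add(ai.residue_number)
        residues[aj.chain_id].add(aj.residue_number)
    return InterfaceSelection(cutoff=cutoff, residues_by_chain=residues,
                              contact_atom_pairs=pairs)
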