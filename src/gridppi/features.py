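"""Non-energy interface features: element densities, SASA/BSA, PSSM, contacts.

Every feature is produced as a :class:`FeaturePointSet` — a named list of
(position, value, sigma) points — which the grid-mapping stage spreads onto
the 3D lattice with Gaussian weights.  Atomic features place one point per
atom with sigma equal to the element's van der Waals radius; residue features
place one point at the residue's alpha-carbon with the carbon radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import (Atom, Complex, InterfaceSelection, StructureError,
                        VDW_RADII, DEFAULT_VDW_RADIUS)
from .forcefield import (ForceFieldTable, assign_parameters,
                         coulomb_energy_per_atom, vdw_energy_per_atom,
                         DegenerateGeometryError, load_forcefield)

__all__ = [
    "FeaturePointSet",
    "SASAResult",
    "PSSMProfile",
    "PSSMFormatError",
    "PSSMAlignmentError",
    "AA_ORDER",
    "THREE_TO_ONE",
    "RESIDUE_CLASSES",
    "atom_density_points",
    "charge_points",
    "energy_points",
    "sasa",
    "bsa",
    "bsa_points",
    "read_pssm",
    "write_pssm",
    "pssm_feature_points",
    "residue_contact_counts",
    "DENSITY_ELEMENTS",
]

#: PSSM column order (one-letter amino-acid codes).
AA_ORDER = list("ARNDCQEGHILKMFPSTWYV")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Default residue classification for contact-count features.
RESIDUE_CLASSES = {
    "charged": set("DEKR"),
    "polar": set("CHNQSTWY"),
    "apolar": set("AFGILMPV"),
}

DENSITY_ELEMENTS = ("C", "N", "O", "S")
CARBON_RADIUS = VDW_RADII["C"]


class PSSMFormatError(ValueError):
    pass


class PSSMAlignmentError(ValueError):
    pass


@dataclass
class FeaturePointSet:
    name: str
    points: list[tuple[np.ndarray, float, float]]  # (position, value, sigma)
    level: str = "atomic"            # "atomic" | "residue"
    chain_tag: str = "shared"        # "A" | "B" | "shared"

    def __post_init__(self):
        if any(s <= 0 for _, _, s in self.points):
            raise ValueError(f"feature {self.name}: sigma must be positive")


@dataclass
class SASAResult:
    per_atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass
class PSSMProfile:
    chain_id: str
    rows: list[tuple]  # (residue_number, one_letter_name, 20 scores, ic)

    def row_for(self, residue_number):
        for row in self.rows:
            if row[0] == residue_number:
                return row
        return None


def _interface_atoms(complex: Complex, selection: InterfaceSelection):
    """(index, Atom) for atoms of interface residues, grouped by chain tag."""
    sel = {(c, r) for c, rs in selection.residues_by_chain.items() for r in rs}
    out = []
    for i, a in enumerate(complex.atoms):
        if a.residue_id in sel:
            out.append((i, a))
    return out


def _chain_tag(complex: Complex, chain_id: str) -> str:
    return "A" if chain_id == complex.chain_ids[0] else "B"


# ---------------------------------------------------------------------------
# Atom density
# ---------------------------------------------------------------------------

def atom_density_points(complex: Complex, selection: InterfaceSelection,
                        table: ForceFieldTable | None = None
                        ) -> list[FeaturePointSet]:
    """One unit-valued point per interface-residue heavy atom, per element.

    Returns 8 channels: elements C, N, O, S for each chain.  Atoms of other
    elements (e.g. hydrogens, selenium) contribute to no density channel.
    """
    radius = (table.radius if table is not None
              else lambda el: VDW_RADII.get(el, DEFAULT_VDW_RADIUS))
    sets: dict[tuple[str, str], FeaturePointSet] = {}
    for tag in ("A", "B"):
        for el in DENSITY_ELEMENTS:
            sets[(el, tag)] = FeaturePointSet(
                name=f"density_{el}_{tag}", points=[], level="atomic", chain_tag=tag)
    for _, a in _interface_atoms(complex, selection):
        if a.element not in DENSITY_ELEMENTS:
            continue
        tag = _chain_tag(complex, a.chain_id)
        sets[(a.element, tag)].points.append(
            (np.asarray(a.position, dtype=float), 1.0, radius(a.element)))
    return [sets[(el, tag)] for tag in ("A", "B") for el in DENSITY_ELEMENTS]


# ---------------------------------------------------------------------------
# Charge / energy point sets (values from the forcefield module)
# ---------------------------------------------------------------------------

def charge_points(complex: Complex, selection: InterfaceSelection,
                  table: ForceFieldTable | None = None) -> list[FeaturePointSet]:
    """Per-chain channels of partial atomic charge at interface atoms."""
    pc = assign_parameters(complex, table)
    return _per_atom_value_points(complex, selection, pc.charge, "charge",
                                  pc.radius)


def energy_points(complex: Complex, selection: InterfaceSelection,
                  table: ForceFieldTable | None = None) -> list[FeaturePointSet]:
    """Per-chain Coulomb and vdW channels (4 total) at interface atoms."""
    tbl = table if table is not None else load_forcefield()
    pc = assign_parameters(complex, tbl)
    coul = coulomb_energy_per_atom(pc, cutoff=tbl.pair_cutoff, clamp=tbl.energy_clamp)
    vdw = vdw_energy_per_atom(pc, cutoff=tbl.pair_cutoff, clamp=tbl.energy_clamp)
    return (_per_atom_value_points(complex, selection, coul, "coulomb", pc.radius)
            + _per_atom_value_points(complex, selection, vdw, "vdw", pc.radius))


def _per_atom_value_points(complex, selection, values, name, radii):
    sets = {tag: FeaturePointSet(name=f"{name}_{tag}", points=[], level="atomic",
                                 chain_tag=tag) for tag in ("A", "B")}
    for i, a in _interface_atoms(complex, selection):
        tag = _chain_tag(complex, a.chain_id)
        sets[tag].points.append(
            (np.asarray(a.position, dtype=float), float(values[i]), float(radii[i])))
    return [sets["A"], sets["B"]]


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    For each atom, the fraction of ``n_points`` quasi-uniform points on its
    probe-expanded sphere that fall inside no other expanded sphere, times
    the sphere area 4*pi*(r+probe)^2.
    """
    import biotite.structure as struc

    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = len(coords)
    if n > 1:
        tree = cKDTree(coords)
        if tree.query_pairs(r=1e-9):
            raise DegenerateGeometryError("coincident atom centers")

    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = np.arange(1, n + 1)
    arr.res_name[:] = "GLY"
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    areas = struc.sasa(arr, probe_radius=probe, point_number=n_points,
                       vdw_radii=radii, ignore_ions=False)
    areas = np.nan_to_num(np.asarray(areas, dtype=float), nan=0.0)
    return SASAResult(per_atom_area=areas, probe_radius=probe,
                      n_sphere_points=n_points)


def bsa(complex: Complex, table: ForceFieldTable | None = None,
        probe: float = 1.4, n_points: int = 960):
    """Buried surface area: (ASA_chainA + ASA_chainB - ASA_complex) / 2.

    Returns ``(total_bsa, per_residue_bsa)`` where the per-residue value is
    the residue's ASA in the isolated chain minus its ASA in the complex,
    floored at zero.
    """
    tbl = table if table is not None else load_forcefield()
    radii = np.array([tbl.radius(a.element) for a in complex.atoms])
    xyz = complex.coords
    asa_complex = sasa(xyz, radii, probe, n_points).per_atom_area
    per_atom_alone = np.zeros(len(complex.atoms))
    for chain in complex.chain_ids:
        idx = complex.chain_atom_indices(chain)
        res = sasa(xyz[idx], radii[idx], probe, n_points)
        per_atom_alone[idx] = res.per_atom_area
    total = float((per_atom_alone.sum() - asa_complex.sum()) / 2.0)
    per_residue: dict[tuple, float] = {}
    for i, a in enumerate(complex.atoms):
        per_residue.setdefault(a.residue_id, 0.0)
        per_residue[a.residue_id] += per_atom_alone[i] - asa_complex[i]
    per_residue = {k: max(0.0, v) for k, v in per_residue.items()}
    return total, per_residue


def _ca_position(complex: Complex, residue_id) -> np.ndarray:
    for a in complex.atoms:
        if a.residue_id == residue_id and a.name == "CA":
            return np.asarray(a.position, dtype=float)
    raise StructureError(f"residue {residue_id} has no alpha carbon")


def bsa_points(complex: Complex, selection: InterfaceSelection,
               table: ForceFieldTable | None = None,
               probe: float = 1.4, n_points: int = 960) -> list[FeaturePointSet]:
    """Per-chain residue-level BSA channels, mapped at the alpha carbons."""
    _, per_residue = bsa(complex, table, probe, n_points)
    sets = {tag: FeaturePointSet(name=f"bsa_{tag}", points=[], level="residue",
                                 chain_tag=tag) for tag in ("A", "B")}
    for chain, residues in selection.residues_by_chain.items():
        tag = _chain_tag(complex, chain)
        for r in sorted(residues, key=str):
            rid = (chain, r)
            sets[tag].points.append(
                (_ca_position(complex, rid), per_residue.get(rid, 0.0), CARBON_RADIUS))
    return [sets["A"], sets["B"]]


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

PSSM_HEADER = ["resnum", "resname"] + AA_ORDER + ["IC"]


def read_pssm(text: str, chain_id: str = "", complex: Complex | None = None
              ) -> PSSMProfile:
    """Read a tab-separated PSSM profile (20 log-odds columns + IC).

    When ``complex`` is given, residue names are validated against the chain
    sequence; a mismatch raises :class:`PSSMAlignmentError` naming the row.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PSSMFormatError("empty PSSM file")
    header = lines[0].split()
    if header != PSSM_HEADER:
        raise PSSMFormatError(
            f"bad PSSM header; expected {' '.join(PSSM_HEADER)!r}")
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != len(PSSM_HEADER):
            raise PSSMFormatError(
                f"PSSM row has {len(parts)} fields, expected {len(PSSM_HEADER)}: {ln!r}")
        resnum_s, resname = parts[0], parts[1]
        resnum = int(resnum_s) if resnum_s.lstrip("-").isdigit() else resnum_s
        scores = tuple(float(x) for x in parts[2:22])
        ic = float(parts[22])
        rows.append((resnum, resname, scores, ic))
    profile = PSSMProfile(chain_id=chain_id, rows=rows)
    if complex is not None and chain_id:
        for pos, (resnum, resname, _, _) in enumerate(profile.rows):
            try:
                three = complex.residue_name_of((chain_id, resnum))
            except KeyError:
                continue
            if THREE_TO_ONE.get(three, "X") != resname:
                raise PSSMAlignmentError(
                    f"PSSM row {pos + 1} (residue {resnum}): profile says "
                    f"{resname}, chain {chain_id} has {three}")
    return profile


def write_pssm(profile: PSSMProfile) -> str:
    lines = ["\t".join(PSSM_HEADER)]
    for resnum, resname, scores, ic in profile.rows:
        fields = [str(resnum), resname] + [format(s, "g") for s in scores] + [format(ic, "g")]
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def pssm_feature_points(complex: Complex, selection: InterfaceSelection,
                        profiles: dict[str, PSSMProfile]) -> list[FeaturePointSet]:
    """20 shared channels, one per residue type column.

    For each interface residue of either chain, each channel gets one point
    at the residue's alpha carbon whose value is that column's log-odds
    score, sigma = carbon vdW radius.  Both chains map into the same
    channels.
    """
    for chain in complex.chain_ids:
        if chain not in profiles:
            raise PSSMAlignmentError(f"no PSSM profile for chain {chain}")
    sets = [FeaturePointSet(name=f"pssm_{aa}", points=[], level="residue",
                            chain_tag="shared") for aa in AA_ORDER]
    for chain in complex.chain_ids:
        profile = profiles[chain]
        for r in sorted(selection.residues_by_chain[chain], key=str):
            row = profile.row_for(r)
            if row is None:
                raise PSSMAlignmentError(
                    f"interface residue {chain}:{r} missing from PSSM profile")
            ca = _ca_position(complex, (chain, r))
            for k in range(20):
                sets[k].points.append((ca, float(row[2][k]), CARBON_RADIUS))
    return sets


# ---------------------------------------------------------------------------
# Residue contact counts (opt-in)
# ---------------------------------------------------------------------------

def _residue_class(one_letter: str, class_table) -> str:
    for cls, members in class_table.items():
        if one_letter in members:
            return cls
    return "apolar"  # unknown residue types are treated as apolar


def residue_contact_counts(complex: Complex, selection: InterfaceSelection,
                           class_table=None) -> list[FeaturePointSet]:
    """Counts of cross-chain residue contacts by partner class (opt-in).

    One channel per chain per class (charged/polar/apolar, 6 total); the
    count for a residue is placed at its alpha carbon.
    """
    classes = class_table if class_table is not None else RESIDUE_CLASSES
    order = list(classes)
    # residue-pair contacts from the atomic contact pairs
    pair_set = set()
    for i, j in selection.contact_atom_pairs:
        ai, aj = complex.atoms[i], complex.atoms[j]
        pair_set.add((ai.residue_id, aj.residue_id))
    counts: dict[tuple, dict[str, int]] = {}
    for rid_a, rid_b in pair_set:
        name_a = THREE_TO_ONE.get(complex.residue_name_of(rid_a), "X")
        name_b = THREE_TO_ONE.get(complex.residue_name_of(rid_b), "X")
        counts.setdefault(rid_a, {c: 0 for c in order})
        counts.setdefault(rid_b, {c: 0 for c in order})
        counts[rid_a][_residue_class(name_b, classes)] += 1
        counts[rid_b][_residue_class(name_a, classes)] += 1
    sets = {(cls, tag): FeaturePointSet(name=f"contacts_{cls}_{tag}", points=[],
                                        level="residue", chain_tag=tag)
            for tag in ("A", "B") for cls in order}
    for chain, residues in selection.residues_by_chain.items():
        tag = _chain_tag(complex, chain)
        for r in sorted(residues, key=str):
            rid = (chain, r)
            ca = _ca_position(complex, rid)
            for cls in order:
                sets[(cls, tag)].points.append(
                    (ca, float(counts.get(rid, {}).get(cls, 0)), CARBON_RADIUS))
    return [sets[(cls, tag)] for tag in ("A", "B") for cls in order]
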