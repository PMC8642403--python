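"""Docking-model quality metrics against a reference structure.

Implements the standard CAPRI-style metrics: ligand RMSD (superpose on the
receptor backbone, measure the ligand backbone), interface RMSD (superpose
on the reference-defined 10 A interface backbone), fraction of native
contacts (5 A heavy-atom residue contacts), the DockQ combination score,
CAPRI quality classes, and the binary near-native label (iRMSD <= 4 A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Complex, StructureError, atomic_contact_pairs

__all__ = [
    "TargetRecord",
    "GeometryError",
    "CorrespondenceError",
    "MetricError",
    "superpose",
    "lrmsd",
    "irmsd",
    "fnat",
    "dockq",
    "capri_class",
    "binary_label",
    "compute_targets",
    "BACKBONE_ATOMS",
    "IRMSD_INTERFACE_CUTOFF",
    "FNAT_CONTACT_CUTOFF",
    "HIT_IRMSD_THRESHOLD",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
IRMSD_INTERFACE_CUTOFF = 10.0   # A, heavy-atom, on the reference
FNAT_CONTACT_CUTOFF = 5.0       # A, heavy-atom, residue-pair level
HIT_IRMSD_THRESHOLD = 4.0       # A


class GeometryError(ValueError):
    pass


class CorrespondenceError(ValueError):
    pass


class MetricError(ValueError):
    pass


@dataclass
class TargetRecord:
    irmsd: float
    lrmsd: float
    fnat: float
    dockq: float
    capri_class: str
    binary_label: int  # 1 = near-native, 0 = wrong

    def as_dict(self) -> dict:
        return {"irmsd": self.irmsd, "lrmsd": self.lrmsd, "fnat": self.fnat,
                "dockq": self.dockq, "capri_class": self.capri_class,
                "binary_class": self.binary_label}


def superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal rigid superposition of P onto Q (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that ``P @ R.T + t``
    minimizes the RMSD to Q; the rotation is proper (det +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("P and Q must be matching n x 3 arrays")
    n = len(P)
    if n < 3:
        raise GeometryError("need at least 3 points to superpose")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    if (np.linalg.matrix_rank(P - Pc, tol=1e-8) < 2
            or np.linalg.matrix_rank(Q - Qc, tol=1e-8) < 2):
        raise GeometryError("rank-deficient (collinear) point sets")
    rot, rssd = Rotation.align_vectors(Q - Qc, P - Pc)
    R = rot.as_matrix()
    t = Qc - Pc @ R.T
    rmsd = float(rssd / np.sqrt(n))
    return R, t, rmsd


def _backbone_index(complex: Complex, chains=None, residues=None):
    """Map (chain, resnum, atom_name) -> atom index for backbone atoms."""
    out = {}
    for i, a in enumerate(complex.atoms):
        if a.name not in BACKBONE_ATOMS:
            continue
        if chains is not None and a.chain_id not in chains:
            continue
        if residues is not None and a.residue_id not in residues:
            continue
        out[(a.chain_id, a.residue_number, a.name)] = i
    return out


def _matched_coords(model: Complex, reference: Complex, chains=None,
                    residues=None):
    """Index-matched backbone coordinate arrays (model, reference).

    Atoms present in only one structure (e.g. missing terminal O) are
    dropped from both.
    """
    mi = _backbone_index(model, chains, residues)
    ri = _backbone_index(reference, chains, residues)
    keys = sorted(set(mi) & set(ri), key=str)
    if not keys:
        raise CorrespondenceError("no matched backbone atoms")
    P = model.coords[[mi[k] for k in keys]]
    Q = reference.coords[[ri[k] for k in keys]]
    return P, Q


def lrmsd(model: Complex, reference: Complex) -> float:
    """Ligand backbone RMSD after superposing on the receptor backbone."""
    rec, lig = reference.receptor_chain, reference.ligand_chain
    P_rec, Q_rec = _matched_coords(model, reference, chains={rec})
    if len(P_rec) < 3:
        raise CorrespondenceError("fewer than 3 matched receptor backbone atoms")
    R, t, _ = superpose(P_rec, Q_rec)
    P_lig, Q_lig = _matched_coords(model, reference, chains={lig})
    diff = (P_lig @ R.T + t) - Q_lig
    return float(np.sqrt((diff ** 2).sum() / len(P_lig)))


def _reference_interface_residues(reference: Complex,
                                  cutoff: float = IRMSD_INTERFACE_CUTOFF):
    heavy = [i for i, a in enumerate(reference.atoms) if a.element != "H"]
    pairs = atomic_contact_pairs(reference, cutoff)
    heavy_set = set(heavy)
    residues = set()
    for i, j in pairs:
        if i in heavy_set and j in heavy_set:
            residues.add(reference.atoms[i].residue_id)
            residues.add(reference.atoms[j].residue_id)
    return residues


def irmsd(model: Complex, reference: Complex) -> float:
    """Interface backbone RMSD.

    Interface residues are defined on the reference with a 10 A heavy-atom
    contact cutoff; the model is superposed onto the reference using those
    residues' backbone atoms and that fit's RMSD is reported.
    """
    residues = _reference_interface_residues(reference)
    if not residues:
        raise MetricError("reference has an empty 10 A interface")
    P, Q = _matched_coords(model, reference, residues=residues)
    _, _, rmsd = superpose(P, Q)
    return rmsd


def _residue_contacts(complex: Complex, cutoff: float) -> set:
    heavy = {i for i, a in enumerate(complex.atoms) if a.element != "H"}
    pairs = atomic_contact_pairs(complex, cutoff)
    out = set()
    for i, j in pairs:
        if i in heavy and j in heavy:
            out.add((complex.atoms[i].residue_id, complex.atoms[j].residue_id))
    return out


def fnat(model: Complex, reference: Complex) -> float:
    """Fraction of the reference's cross-chain residue contacts kept by the model."""
    native = _residue_contacts(reference, FNAT_CONTACT_CUTOFF)
    if not native:
        raise MetricError("reference has zero native contacts")
    model_contacts = _residue_contacts(model, FNAT_CONTACT_CUTOFF)
    return len(native & model_contacts) / len(native)


def dockq(fnat_value: float, lrmsd_value: float, irmsd_value: float) -> float:
    """DockQ = (FNAT + 1/(1+(iRMSD/1.5)^2) + 1/(1+(lRMSD/8.5)^2)) / 3."""
    if fnat_value < 0 or lrmsd_value < 0 or irmsd_value < 0:
        raise ValueError("dockq inputs must be non-negative")
    return (fnat_value
            + 1.0 / (1.0 + (irmsd_value / 1.5) ** 2)
            + 1.0 / (1.0 + (lrmsd_value / 8.5) ** 2)) / 3.0


def capri_class(fnat_value: float, lrmsd_value: float, irmsd_value: float) -> str:
    """CAPRI quality tier from the conventional threshold table (inclusive)."""
    if fnat_value >= 0.5 and (irmsd_value <= 1.0 or lrmsd_value <= 1.0):
        return "high"
    if fnat_value >= 0.3 and (irmsd_value <= 2.0 or lrmsd_value <= 5.0):
        return "medium"
    if fnat_value >= 0.1 and (irmsd_value <= 4.0 or lrmsd_value <= 10.0):
        return "acceptable"
    return "incorrect"


def binary_label(irmsd_value: float, threshold: float = HIT_IRMSD_THRESHOLD) -> int:
    """1 (near-native) iff iRMSD <= threshold, else 0 (wrong)."""
    if irmsd_value < 0:
        raise ValueError("irmsd must be non-negative")
    return int(irmsd_value <= threshold)


def compute_targets(model: Complex, reference: Complex) -> TargetRecord:
    i = irmsd(model, reference)
    l = lrmsd(model, reference)
    f = fnat(model, reference)
    return TargetRecord(irmsd=i, lrmsd=l, fnat=f, dockq=dockq(f, l, i),
                        capri_class=capri_class(f, l, i),
                        binary_label=binary_label(i))
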