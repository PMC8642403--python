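"""Reduced force field: parameter assignment and intermolecular energies.

Per-atom Coulomb and Lennard-Jones feature values are the sums of all
pairwise cross-chain interaction terms within a hard cutoff (default 8.5 A):
``v_k = sum_l v_kl``.  Each pair term is clamped to +-energy_clamp so that
steric clashes in rigid-body models cannot dominate the feature grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure import Complex, StructureError, VDW_RADII, DEFAULT_VDW_RADIUS

__all__ = [
    "ForceFieldTable",
    "ParameterizedComplex",
    "ParameterError",
    "DegenerateGeometryError",
    "load_forcefield",
    "assign_parameters",
    "coulomb_energy_per_atom",
    "vdw_energy_per_atom",
    "COULOMB_CONSTANT",
]

#: Coulomb conversion constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

DEFAULT_PAIR_CUTOFF = 8.5
DEFAULT_ENERGY_CLAMP = 1000.0


class ParameterError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class ForceFieldTable:
    charge_map: dict[tuple[str, str], float]
    vdw_map: dict[str, tuple[float, float]]          # element -> (epsilon, sigma)
    vdw_radius_map: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    default_radius: float = DEFAULT_VDW_RADIUS
    coulomb_constant: float = COULOMB_CONSTANT
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF
    energy_clamp: float = DEFAULT_ENERGY_CLAMP

    def __post_init__(self):
        for el, (eps, sig) in self.vdw_map.items():
            if eps < 0 or sig <= 0:
                raise ParameterError(f"invalid LJ parameters for {el}: {(eps, sig)}")
        if any(r <= 0 for r in self.vdw_radius_map.values()):
            raise ParameterError("vdW radii must be positive")
        if self.pair_cutoff <= 0:
            raise ParameterError("pair cutoff must be positive")

    def radius(self, element: str) -> float:
        return self.vdw_radius_map.get(element, self.default_radius)


@dataclass
class ParameterizedComplex:
    """A Complex with per-atom charge, LJ epsilon/sigma and vdW radius arrays."""

    complex: Complex
    charge: np.ndarray
    epsilon: np.ndarray
    sigma: np.ndarray
    radius: np.ndarray
    unknown_atoms: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_warnings(self) -> int:
        return len(self.unknown_atoms)


def load_forcefield(path=None) -> ForceFieldTable:
    """Load a parameter table; the shipped reduced table by default.

    Dialect: '#' comments; ``[charges]`` lines are ``RES ATOM q``;
    ``[lj]`` lines are ``ELEMENT epsilon sigma``.
    """
    if path is None:
        text = (resources.files("gridppi") / "data" / "reduced_ff.params").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    charge_map: dict[tuple[str, str], float] = {}
    vdw_map: dict[str, tuple[float, float]] = {}
    section = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        parts = line.split()
        if section == "charges":
            if len(parts) != 3:
                raise ParameterError(f"bad [charges] line: {raw!r}")
            charge_map[(parts[0].upper(), parts[1].upper())] = float(parts[2])
        elif section == "lj":
            if len(parts) != 3:
                raise ParameterError(f"bad [lj] line: {raw!r}")
            vdw_map[parts[0].upper()] = (float(parts[1]), float(parts[2]))
        else:
            raise ParameterError(f"line outside a known section: {raw!r}")
    return ForceFieldTable(charge_map=charge_map, vdw_map=vdw_map)


def assign_parameters(complex: Complex, table: ForceFieldTable | None = None
                      ) -> ParameterizedComplex:
    """Assign charge/LJ/radius parameters to every atom.

    Unknown (residue, atom) keys fall back to charge 0 with the element's
    LJ parameters, and are recorded in ``unknown_atoms``.  An element absent
    from the LJ table falls back to carbon; an element with no radius uses
    the default 1.70 A.
    """
    if table is None:
        table = load_forcefield()
    n = len(complex.atoms)
    charge = np.zeros(n)
    epsilon = np.zeros(n)
    sigma = np.zeros(n)
    radius = np.zeros(n)
    unknown: list[tuple[str, str]] = []
    if "C" not in table.vdw_map:
        raise ParameterError("LJ table must at least parameterize carbon")
    for i, a in enumerate(complex.atoms):
        key = (a.residue_name.upper(), a.name.upper())
        if key in table.charge_map:
            charge[i] = table.charge_map[key]
        else:
            unknown.append(key)
        eps, sig = table.vdw_map.get(a.element, table.vdw_map["C"])
        epsilon[i], sigma[i] = eps, sig
        radius[i] = table.radius(a.element)
    return ParameterizedComplex(complex=complex, charge=charge, epsilon=epsilon,
                                sigma=sigma, radius=radius, unknown_atoms=unknown)


def _cross_chain_pairs(pc: ParameterizedComplex, cutoff: float):
    mask = pc.complex.chain_mask
    idx_a = np.flatnonzero(mask)
    idx_b = np.flatnonzero(~mask)
    xyz = pc.complex.coords
    tree = cKDTree(xyz[idx_b])
    out_i, out_j, out_r = [], [], []
    for ia, nbrs in zip(idx_a, tree.query_ball_point(xyz[idx_a], r=cutoff)):
        for jb in nbrs:
            j = int(idx_b[jb])
            r = float(np.linalg.norm(xyz[ia] - xyz[j]))
            if r == 0.0:
                raise DegenerateGeometryError(
                    f"atoms {pc.complex.atoms[ia].serial} and "
                    f"{pc.complex.atoms[j].serial} coincide"
                )
            out_i.append(int(ia)); out_j.append(j); out_r.append(r)
    return (np.array(out_i, dtype=int), np.array(out_j, dtype=int),
            np.array(out_r, dtype=float))


def _accumulate(n: int, i: np.ndarray, j: np.ndarray, e: np.ndarray) -> np.ndarray:
    v = np.zeros(n)
    np.add.at(v, i, e)
    np.add.at(v, j, e)
    return v


def coulomb_energy_per_atom(pc: ParameterizedComplex,
                            cutoff: float = DEFAULT_PAIR_CUTOFF,
                            clamp: float = DEFAULT_ENERGY_CLAMP) -> np.ndarray:
    """Per-atom summed intermolecular Coulomb energy (kcal/mol).

    v_k = sum over cross-chain partners within cutoff of C q_k q_l / r_kl,
    each pair term clamped to +-clamp; intra-chain pairs excluded.
    """
    i, j, r = _cross_chain_pairs(pc, cutoff)
    if len(i) == 0:
        return np.zeros(len(pc.complex.atoms))
    e = COULOMB_CONSTANT * pc.charge[i] * pc.charge[j] / r
    e = np.clip(e, -clamp, clamp)
    return _accumulate(len(pc.complex.atoms), i, j, e)


def vdw_energy_per_atom(pc: ParameterizedComplex,
                        cutoff: float = DEFAULT_PAIR_CUTOFF,
                        clamp: float = DEFAULT_ENERGY_CLAMP) -> np.ndarray:
    """Per-atom summed intermolecular Lennard-Jones energy (kcal/mol).

    4 eps_kl [ (sig_kl/r)^12 - (sig_kl/r)^6 ] with Lorentz-Berthelot
    combining (arithmetic sigma, geometric epsilon), per-pair clamped.
    """
    i, j, r = _cross_chain_pairs(pc, cutoff)
    if len(i) == 0:
        return np.zeros(len(pc.complex.atoms))
    sig = 0.5 * (pc.sigma[i] + pc.sigma[j])
    eps = np.sqrt(pc.epsilon[i] * pc.epsilon[j])
    sr6 = (sig / r) ** 6
    e = 4.0 * eps * (sr6 ** 2 - sr6)
    e = np.clip(e, -clamp, clamp)
    return _accumulate(len(pc.complex.atoms), i, j, e)
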