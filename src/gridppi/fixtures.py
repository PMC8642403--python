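"""Self-contained synthetic inputs: toy dimers, rigid-body decoy sets,
synthetic PSSM profiles, and planted-signal grid datasets.

These generators stand in for real docking pipelines at desk scale.  A toy
dimer is a pair of idealized backbone traces (N, CA, C, O at standard-ish
geometry, 3.8 A alpha-carbon spacing) placed so the chains touch within the
5.5 A interface cutoff.  Decoys perturb only the ligand chain with a seeded
rigid rotation + translation, mimicking rigid-body docking diversity, and
rejection-resample until requested counts of near-native (iRMSD <= 4 A) and
wrong decoys exist.  Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Atom, Complex
from .features import PSSMProfile, AA_ORDER, ONE_TO_THREE
from .gridmap import GridSpec, FeatureGrid, default_channel_names, make_grid
from .store import DatasetEntry, write_entries
from .targets import irmsd, HIT_IRMSD_THRESHOLD

__all__ = [
    "DecoySpec",
    "DecoyRecord",
    "GenerationError",
    "make_toy_dimer",
    "make_decoys",
    "make_synthetic_pssm",
    "make_planted_grid_dataset",
]


class GenerationError(RuntimeError):
    pass


@dataclass
class DecoySpec:
    n_decoys: int = 50
    max_translation: float = 20.0    # A
    max_rotation: float = 80.0       # degrees
    seed: int = 0
    guarantee: tuple[int, int] = (5, 5)   # (min near-native, min wrong)

    def __post_init__(self):
        if self.max_translation < 0 or self.max_rotation < 0:
            raise ValueError("perturbation magnitudes must be >= 0")
        if sum(self.guarantee) > self.n_decoys:
            raise ValueError("guarantee counts exceed n_decoys")


@dataclass
class DecoyRecord:
    """What was done to the ligand chain of one decoy."""
    decoy_id: str
    rotation_deg: float
    translation: tuple[float, float, float]
    displacement: float    # mean ligand-atom displacement, A
    irmsd: float
    label: int


# backbone atom offsets relative to CA, roughly standard bond geometry
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.60, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.20, 0.60, 0.00]),
    "O": np.array([1.35, 1.80, 0.20]),
}


def make_toy_dimer(n_res_per_chain: int = 5, seed: int = 0) -> Complex:
    """Two idealized backbone chains with a guaranteed 5.5 A interface.

    Each residue contributes N, CA, C, O (4 atoms); chain A runs along x at
    z = 0, chain B parallel at z ~ 4.2 A with a half-residue stagger, so at
    least one cross-chain atom pair is well inside the interface cutoff.
    Residue types are drawn from the seeded generator.
    """
    if n_res_per_chain < 3:
        raise ValueError("need at least 3 residues per chain")
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    aa_codes = rng.choice(AA_ORDER, size=2 * n_res_per_chain)
    for ci, (chain, z_off, x_off, y_flip) in enumerate(
            [("A", 0.0, 0.0, 1.0), ("B", 4.2, 1.9, -1.0)]):
        for r in range(n_res_per_chain):
            ca = np.array([x_off + 3.8 * r, 0.0, z_off])
            jitter = rng.normal(0.0, 0.05, size=(4, 3))
            resname = ONE_TO_THREE[aa_codes[ci * n_res_per_chain + r]]
            for k, name in enumerate(("N", "CA", "C", "O")):
                off = _BACKBONE_OFFSETS[name] * np.array([1.0, y_flip, 1.0])
                pos = ca + off + jitter[k]
                atoms.append(Atom(serial=serial, name=name,
                                  element=name[0], chain_id=chain,
                                  residue_number=r + 1, residue_name=resname,
                                  position=tuple(pos)))
                serial += 1
    return Complex(atoms, source_id=f"toy_dimer_n{n_res_per_chain}_s{seed}")


def _perturb_ligand(reference: Complex, angle_deg: float, axis: np.ndarray,
                    translation: np.ndarray) -> Complex:
    lig = reference.ligand_chain
    lig_idx = reference.chain_atom_indices(lig)
    centroid = reference.coords[lig_idx].mean(axis=0)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    new_xyz = reference.coords.copy()
    new_xyz[lig_idx] = ((new_xyz[lig_idx] - centroid) @ R.T + centroid
                        + translation)
    atoms = [Atom(a.serial, a.name, a.element, a.chain_id, a.residue_number,
                  a.residue_name, tuple(p))
             for a, p in zip(reference.atoms, new_xyz)]
    return Complex(atoms, source_id=reference.source_id)


def make_decoys(reference: Complex, spec: DecoySpec
                ) -> list[tuple[Complex, DecoyRecord]]:
    """Rigid-body decoys of the reference with a quality spread.

    Each decoy rotates the ligand chain about its centroid by up to
    ``max_rotation`` degrees and translates it by up to ``max_translation``
    A, both scaled by a shared uniform draw so qualities span the range.
    Candidates are rejection-resampled until at least ``guarantee[0]``
    near-native and ``guarantee[1]`` wrong decoys exist.
    """
    rng = np.random.default_rng(spec.seed)
    lig_idx = reference.chain_atom_indices(reference.ligand_chain)
    need_pos, need_neg = spec.guarantee
    out: list[tuple[Complex, DecoyRecord]] = []
    n_pos = n_neg = 0
    max_attempts = max(100 * spec.n_decoys, 1)
    for _ in range(max_attempts):
        if len(out) == spec.n_decoys:
            break
        u = rng.uniform()
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        angle = u * spec.max_rotation
        translation = u * spec.max_translation * direction
        decoy = _perturb_ligand(reference, angle, axis, translation)
        value = irmsd(decoy, reference)
        label = int(value <= HIT_IRMSD_THRESHOLD)
        rem_pos = max(0, need_pos - n_pos)
        rem_neg = max(0, need_neg - n_neg)
        slots = spec.n_decoys - len(out)
        if label == 1 and rem_pos == 0 and slots <= rem_neg:
            continue
        if label == 0 and rem_neg == 0 and slots <= rem_pos:
            continue
        disp = float(np.linalg.norm(
            decoy.coords[lig_idx] - reference.coords[lig_idx], axis=1).mean())
        rec = DecoyRecord(decoy_id=f"decoy_{len(out):04d}",
                          rotation_deg=float(angle),
                          translation=tuple(float(t) for t in translation),
                          displacement=disp, irmsd=float(value), label=label)
        out.append((decoy, rec))
        n_pos += label
        n_neg += 1 - label
    if len(out) < spec.n_decoys or n_pos < need_pos or n_neg < need_neg:
        raise GenerationError(
            f"could not satisfy decoy guarantees within {max_attempts} attempts "
            f"(got {n_pos} near-native, {n_neg} wrong)")
    return out


def make_synthetic_pssm(complex: Complex, chain_id: str, seed: int = 0
                        ) -> PSSMProfile:
    """A random but self-consistent PSSM profile for one chain.

    Integer log-odds are uniform in [-5, 8] with the residue's own column
    biased by +4; information content is uniform in [0, 2].
    """
    from .features import THREE_TO_ONE
    if chain_id not in complex.chain_ids:
        raise ValueError(f"no chain {chain_id!r} in {complex.source_id!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for rid in complex.residues(chain_id):
        resname = THREE_TO_ONE.get(complex.residue_name_of(rid), "A")
        scores = rng.integers(-5, 9, size=20).astype(float)
        own = AA_ORDER.index(resname)
        scores[own] += 4.0
        ic = float(np.round(rng.uniform(0.0, 2.0), 3))
        rows.append((rid[1], resname, tuple(scores), ic))
    return PSSMProfile(chain_id=chain_id, rows=rows)


def make_planted_grid_dataset(path, n_pos: int, n_neg: int, snr: float,
                              seed: int = 0, n_grid: int = 12,
                              resolution: float = 1.0,
                              signal_channel: str = "density_C_A",
                              n_cases: int = 5) -> list[str]:
    """Write an HDF5 dataset of noise grids with a planted class signal.

    Every entry has the default 36-channel layout filled with unit-variance
    Gaussian noise; positive entries additionally carry a Gaussian blob of
    amplitude ``snr`` (width 3 grid units, centered) in ``signal_channel``.
    Labels are stored as the ``binary_class`` target.  Returns the model ids.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one entry per class")
    if snr < 0:
        raise ValueError("snr must be >= 0")
    rng = np.random.default_rng(seed)
    names = default_channel_names()
    if signal_channel not in names:
        raise ValueError(f"unknown channel {signal_channel!r}")
    spec = make_grid((0.0, 0.0, 0.0),
                     size=tuple(n_grid * resolution for _ in range(3)),
                     resolution=resolution)
    ax = [spec.axis_coords(i) for i in range(3)]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    blob = np.exp(-d2 / (2.0 * 3.0 ** 2))

    labels = np.array([1] * n_pos + [0] * n_neg)
    order = rng.permutation(len(labels))
    labels = labels[order]
    entries = []
    ids = []
    for i, label in enumerate(labels):
        channels = {}
        for name in names:
            arr = rng.normal(0.0, 1.0, size=spec.shape)
            if label == 1 and name == signal_channel:
                arr = arr + snr * blob
            channels[name] = arr
        grid = FeatureGrid(spec=spec, channels=channels,
                           source_id=f"planted_{i:04d}")
        model_id = f"planted_{i:04d}"
        ids.append(model_id)
        entries.append(DatasetEntry(
            model_id=model_id, case_id=f"case_{i % n_cases}", grid=grid,
            targets={"binary_class": int(label)}, seed=seed))
    write_entries(path, entries)
    return ids
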