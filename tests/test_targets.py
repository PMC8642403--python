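import numpy as np
import pytest
from scipy.stats import spearmanr

import gridppi as g
from gridppi.structure import Atom, Complex
from gridppi.targets import (GeometryError, MetricError, superpose, lrmsd,
                             irmsd, fnat, dockq, capri_class, binary_label)

from conftest import rigid_transform


def kabsch_oracle(P, Q):
    """Independent SVD-based optimal superposition RMSD."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = Pc @ R.T - Qc
    return np.sqrt((diff ** 2).sum() / len(P))


class TestSuperpose:
    def test_identical_points_have_zero_rmsd(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    def test_pure_translation_recovered(self):
        P = np.random.default_rng(1).normal(size=(6, 3))
        R, t, rmsd = superpose(P, P + [5.0, 0.0, 0.0])
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(t, [5.0, 0.0, 0.0], atol=1e-7)

    def test_beats_brute_force_rotation_grid(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(2)
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        _, _, rmsd = superpose(P, Q)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        mats = Rotation.random(100_000, rng=rng).as_matrix()
        rotated = np.einsum("rij,nj->rni", mats, Pc)
        brute = np.sqrt(((rotated - Qc) ** 2).sum(axis=(1, 2)) / len(P)).min()
        assert rmsd <= brute + 1e-9
        assert rmsd == pytest.approx(kabsch_oracle(P, Q), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError):
            superpose(line, line)


class TestRMSDMetrics:
    def test_self_comparison_is_zero(self, dimer):
        assert lrmsd(dimer, dimer) == pytest.approx(0.0, abs=1e-7)
        assert irmsd(dimer, dimer) == pytest.approx(0.0, abs=1e-7)
        assert fnat(dimer, dimer) == 1.0

    def test_rigidly_moved_model_scores_perfect(self, dimer):
        moved = rigid_transform(dimer, seed=3)
        assert lrmsd(moved, dimer) == pytest.approx(0.0, abs=1e-6)
        assert irmsd(moved, dimer) == pytest.approx(0.0, abs=1e-6)
        assert fnat(moved, dimer) == 1.0

    def test_pure_ligand_translation_equals_lrmsd(self, dimer):
        lig = dimer.ligand_chain
        atoms = [a if a.chain_id != lig else
                 Atom(a.serial, a.name, a.element, a.chain_id,
                      a.residue_number, a.residue_name,
                      (a.position[0], a.position[1], a.position[2] + 2.0))
                 for a in dimer.atoms]
        assert lrmsd(Complex(atoms), dimer) == pytest.approx(2.0, abs=1e-9)

    def test_far_displaced_ligand_has_zero_fnat(self, dimer):
        lig = dimer.ligand_chain
        atoms = [a if a.chain_id != lig else
                 Atom(a.serial, a.name, a.element, a.chain_id,
                      a.residue_number, a.residue_name,
                      (a.position[0] + 100.0, *a.position[1:]))
                 for a in dimer.atoms]
        assert fnat(Complex(atoms), dimer) == 0.0

    def test_metrics_match_independent_recomputation(self, dimer, decoy_set):
        for decoy, rec in decoy_set[:3]:
            # iRMSD oracle: explicit 10 A interface residue list + Kabsch
            iface = set()
            for a in dimer.atoms:
                for b in dimer.atoms:
                    if a.chain_id == "A" and b.chain_id == "B":
                        d = np.linalg.norm(np.array(a.position) - b.position)
                        if d <= 10.0:
                            iface.add(a.residue_id)
                            iface.add(b.residue_id)
            keys = [(a.chain_id, a.residue_number, a.name)
                    for a in dimer.atoms
                    if a.residue_id in iface and a.name in ("N", "CA", "C", "O")]
            ref_xyz = {(a.chain_id, a.residue_number, a.name): a.position
                       for a in dimer.atoms}
            mod_xyz = {(a.chain_id, a.residue_number, a.name): a.position
                       for a in decoy.atoms}
            P = np.array([mod_xyz[k] for k in keys])
            Q = np.array([ref_xyz[k] for k in keys])
            assert irmsd(decoy, dimer) == pytest.approx(
                kabsch_oracle(P, Q), abs=1e-6)
            # FNAT oracle: explicit contact enumeration at 5 A
            def contacts(c):
                out = set()
                for a in c.atoms:
                    for b in c.atoms:
                        if a.chain_id == "A" and b.chain_id == "B":
                            d = np.linalg.norm(np.array(a.position) - b.position)
                            if d <= 5.0:
                                out.add((a.residue_number, b.residue_number))
                return out
            native = contacts(dimer)
            assert fnat(decoy, dimer) == pytest.approx(
                len(native & contacts(decoy)) / len(native), abs=1e-12)
            # lRMSD oracle: fit receptor backbone, measure ligand backbone
            rec_keys = [k for k in ref_xyz
                        if k[0] == dimer.receptor_chain and
                        k[2] in ("N", "CA", "C", "O")]
            lig_keys = [k for k in ref_xyz
                        if k[0] == dimer.ligand_chain and
                        k[2] in ("N", "CA", "C", "O")]
            Pr = np.array([mod_xyz[k] for k in rec_keys])
            Qr = np.array([ref_xyz[k] for k in rec_keys])
            Pc, Qc = Pr - Pr.mean(0), Qr - Qr.mean(0)
            H = Pc.T @ Qc
            U, S, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
            t = Qr.mean(0) - Pr.mean(0) @ R.T
            Pl = np.array([mod_xyz[k] for k in lig_keys]) @ R.T + t
            Ql = np.array([ref_xyz[k] for k in lig_keys])
            oracle = np.sqrt(((Pl - Ql) ** 2).sum() / len(Pl))
            assert lrmsd(decoy, dimer) == pytest.approx(oracle, abs=1e-6)

    def test_decoy_irmsd_tracks_displacement(self, decoy_set):
        ir = [rec.irmsd for _, rec in decoy_set]
        disp = [rec.displacement for _, rec in decoy_set]
        assert spearmanr(ir, disp).statistic > 0.9


class TestFnatEnumeration:
    def test_three_of_four_native_contacts_preserved(self):
        ref_atoms, mod_atoms = [], []
        for i in range(4):
            a = Atom(i + 1, "CA", "C", "A", i + 1, "GLY", (20.0 * i, 0.0, 0.0))
            b = Atom(i + 5, "CA", "C", "B", i + 1, "GLY", (20.0 * i, 4.0, 0.0))
            ref_atoms += [a, b]
            if i == 3:
                b = Atom(b.serial, b.name, b.element, b.chain_id,
                         b.residue_number, b.residue_name, (20.0 * i, 50.0, 0.0))
            mod_atoms += [a, b]
        assert fnat(Complex(mod_atoms), Complex(ref_atoms)) == 0.75


class TestScores:
    def test_dockq_perfect_model(self):
        assert dockq(1.0, 0.0, 0.0) == 1.0

    def test_dockq_at_scale_constants(self):
        assert dockq(0.5, 8.5, 1.5) == pytest.approx(0.5, abs=1e-12)

    def test_dockq_vanishes_for_distant_models(self):
        assert dockq(0.0, 1e6, 1e6) < 1e-9

    def test_dockq_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            f, l, i = rng.uniform(0, 1), rng.uniform(0, 20), rng.uniform(0, 10)
            base = dockq(f, l, i)
            assert dockq(min(1.0, f + 0.1), l, i) >= base
            assert dockq(f, max(0.0, l - 1.0), i) >= base
            assert dockq(f, l, max(0.0, i - 1.0)) >= base

    @pytest.mark.parametrize("f,l,i,expected", [
        (1.0, 0.0, 0.0, "high"),
        (0.05, 20.0, 8.0, "incorrect"),
        (0.1, 10.0, 4.0, "acceptable"),
        (0.4, 4.0, 1.5, "medium"),
    ])
    def test_capri_class_thresholds(self, f, l, i, expected):
        assert capri_class(f, l, i) == expected

    @pytest.mark.parametrize("value,expected", [
        (4.0, 1), (4.0001, 0), (0.0, 1)])
    def test_binary_label_boundary(self, value, expected):
        assert binary_label(value) == expected

    def test_empty_native_interface_raises(self):
        a = Complex([Atom(1, "CA", "C", "A", 1, "GLY", (0, 0, 0)),
                     Atom(2, "CA", "C", "B", 1, "GLY", (500, 0, 0))])
        with pytest.raises(MetricError):
            fnat(a, a)
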