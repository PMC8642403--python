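import numpy as np
import pytest

import gridppi as g
from gridppi.features import (PSSMFormatError, PSSMAlignmentError, PSSMProfile,
                              atom_density_points, residue_contact_counts,
                              read_pssm, write_pssm, AA_ORDER)
from gridppi.structure import Atom, Complex, interface_residues

from conftest import rigid_transform


class TestAtomDensity:
    def test_counts_points_per_element_and_excludes_non_interface(self):
        # chain A residue 1 (1 N + 2 C) close to chain B; A residue 2 far away
        atoms = [
            Atom(1, "N", "N", "A", 1, "GLY", (0.0, 0.0, 0.0)),
            Atom(2, "CA", "C", "A", 1, "GLY", (1.5, 0.0, 0.0)),
            Atom(3, "C", "C", "A", 1, "GLY", (2.5, 1.0, 0.0)),
            Atom(4, "CA", "C", "A", 2, "GLY", (50.0, 0.0, 0.0)),
            Atom(5, "CA", "C", "B", 1, "GLY", (0.0, 4.0, 0.0)),
        ]
        c = Complex(atoms)
        sel = interface_residues(c, 5.5)
        sets = {ps.name: ps for ps in atom_density_points(c, sel)}
        assert len(sets) == 8
        assert len(sets["density_N_A"].points) == 1
        assert len(sets["density_C_A"].points) == 2
        assert len(sets["density_C_B"].points) == 1
        assert all(v == 1.0 for _, v, _ in sets["density_C_A"].points)
        assert all(s == 1.70 for _, _, s in sets["density_C_A"].points)
        assert all(s == 1.55 for _, _, s in sets["density_N_A"].points)
        # far residue A:2 contributes nowhere
        assert sum(len(ps.points) for ps in sets.values()) == 4


class TestSASA:
    def test_isolated_sphere_matches_analytic_area(self):
        res = g.sasa(np.zeros((1, 3)), np.array([1.7]), probe=1.4, n_points=960)
        analytic = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert res.total == pytest.approx(analytic, rel=0.01)

    def test_caged_atom_is_buried(self):
        # central atom enclosed by a tight cubic cage of 26 neighbours
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
        coords = np.vstack([[0.0, 0.0, 0.0], 2.0 * np.array(offsets)])
        radii = np.full(len(coords), 1.7)
        res = g.sasa(coords, radii, probe=1.4, n_points=960)
        assert res.per_atom_area[0] == 0.0

    def test_two_sphere_overlap_matches_monte_carlo(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.7, 1.5])
        probe = 1.4
        res = g.sasa(coords, radii, probe=probe, n_points=960)
        rng = np.random.default_rng(42)
        expanded = radii + probe
        mc_total = 0.0
        for k in range(2):
            pts = rng.normal(size=(10 ** 6, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[k] + expanded[k] * pts
            other = 1 - k
            outside = np.linalg.norm(pts - coords[other], axis=1) > expanded[other]
            mc_total += outside.mean() * 4.0 * np.pi * expanded[k] ** 2
        assert res.total == pytest.approx(mc_total, rel=0.02)

    def test_convergence_with_point_count(self, dimer):
        table = g.load_forcefield()
        radii = np.array([table.radius(a.element) for a in dimer.atoms])
        t1 = g.sasa(dimer.coords, radii, n_points=960).total
        t2 = g.sasa(dimer.coords, radii, n_points=1920).total
        assert abs(t2 - t1) / t1 < 0.01

    def test_coincident_centers_rejected(self):
        from gridppi.forcefield import DegenerateGeometryError
        with pytest.raises(DegenerateGeometryError):
            g.sasa(np.zeros((2, 3)), np.array([1.7, 1.7]))


class TestBSA:
    def test_distant_chains_bury_nothing(self):
        atoms = [Atom(1, "CA", "C", "A", 1, "GLY", (0.0, 0.0, 0.0)),
                 Atom(2, "CA", "C", "B", 1, "GLY", (100.0, 0.0, 0.0))]
        total, per_res = g.bsa(Complex(atoms))
        assert total == pytest.approx(0.0, abs=1e-6)
        assert all(v == pytest.approx(0.0, abs=1e-6) for v in per_res.values())

    def test_equals_half_asa_difference(self, dimer):
        table = g.load_forcefield()
        radii = np.array([table.radius(a.element) for a in dimer.atoms])
        asa_complex = g.sasa(dimer.coords, radii).total
        asa_chains = 0.0
        for chain in dimer.chain_ids:
            idx = dimer.chain_atom_indices(chain)
            asa_chains += g.sasa(dimer.coords[idx], radii[idx]).total
        total, _ = g.bsa(dimer)
        assert total == pytest.approx((asa_chains - asa_complex) / 2.0, abs=1e-9)

    def test_non_negative_and_rigid_invariant(self, dimer):
        t0, _ = g.bsa(dimer)
        t1, _ = g.bsa(rigid_transform(dimer, seed=5))
        assert t0 >= 0.0
        assert t1 == pytest.approx(t0, rel=0.02)


class TestPSSM:
    def test_round_trip_is_exact(self, dimer):
        profile = g.make_synthetic_pssm(dimer, "A", seed=3)
        back = read_pssm(write_pssm(profile), chain_id="A", complex=dimer)
        assert back.rows == profile.rows
        assert len(back.rows) == 5
        assert all(len(r[2]) == 20 for r in back.rows)

    def test_wrong_column_count_rejected(self, dimer):
        text = write_pssm(g.make_synthetic_pssm(dimer, "A", seed=3))
        lines = text.splitlines()
        lines[1] = "\t".join(lines[1].split("\t")[:-2])  # drop a score + IC
        with pytest.raises(PSSMFormatError):
            read_pssm("\n".join(lines))

    def test_residue_mismatch_names_position(self, dimer):
        profile = g.make_synthetic_pssm(dimer, "A", seed=3)
        rows = list(profile.rows)
        wrong = "K" if rows[2][1] != "K" else "M"
        rows[2] = (rows[2][0], wrong, rows[2][2], rows[2][3])
        text = write_pssm(PSSMProfile("A", rows))
        with pytest.raises(PSSMAlignmentError, match="row 3"):
            read_pssm(text, chain_id="A", complex=dimer)


class TestPSSMFeatures:
    def test_single_interface_residue_gives_one_point_per_channel(self):
        atoms = [
            Atom(1, "CA", "C", "A", 1, "ALA", (0.0, 0.0, 0.0)),
            Atom(2, "CA", "C", "B", 1, "GLY", (0.0, 4.0, 0.0)),
        ]
        c = Complex(atoms)
        sel = interface_residues(c, 5.5)
        profiles = {ch: g.make_synthetic_pssm(c, ch, seed=1) for ch in "AB"}
        sets = g.pssm_feature_points(c, sel, profiles)
        assert len(sets) == 20
        assert all(len(ps.points) == 2 for ps in sets)  # one residue per chain

    def test_all_zero_profile_maps_to_zero_channels(self, dimer):
        zero = {ch: PSSMProfile(ch, [(r[1], g.features.THREE_TO_ONE[
            dimer.residue_name_of(r)], (0.0,) * 20, 0.0)
            for r in dimer.residues(ch)]) for ch in dimer.chain_ids}
        sel = interface_residues(dimer)
        sets = g.pssm_feature_points(dimer, sel, zero)
        assert all(v == 0.0 for ps in sets for _, v, _ in ps.points)

    def test_chain_label_swap_leaves_shared_channels_unchanged(self, dimer,
                                                               profiles):
        sel = interface_residues(dimer)
        sets0 = g.pssm_feature_points(dimer, sel, profiles)
        swapped = Complex([
            Atom(a.serial, a.name, a.element, {"A": "B", "B": "A"}[a.chain_id],
                 a.residue_number, a.residue_name, a.position)
            for a in dimer.atoms])
        swapped_profiles = {"A": PSSMProfile("A", profiles["B"].rows),
                            "B": PSSMProfile("B", profiles["A"].rows)}
        sel1 = interface_residues(swapped)
        sets1 = g.pssm_feature_points(swapped, sel1, swapped_profiles)
        for ps0, ps1 in zip(sets0, sets1):
            pts0 = sorted((tuple(np.round(p, 6)), v) for p, v, _ in ps0.points)
            pts1 = sorted((tuple(np.round(p, 6)), v) for p, v, _ in ps1.points)
            assert pts0 == pts1

    def test_missing_interface_residue_raises_alignment_error(self, dimer,
                                                              profiles):
        sel = interface_residues(dimer)
        truncated = {
            "A": PSSMProfile("A", profiles["A"].rows[:1]),
            "B": profiles["B"],
        }
        with pytest.raises(PSSMAlignmentError):
            g.pssm_feature_points(dimer, sel, truncated)


class TestContactCounts:
    def test_partner_class_enumeration(self):
        # B residue 1 contacts: 2 charged (ASP, LYS) + 1 polar (SER) on chain A
        atoms = [
            Atom(1, "CA", "C", "A", 1, "ASP", (0.0, 0.0, 0.0)),
            Atom(2, "CA", "C", "A", 2, "LYS", (3.0, 0.0, 0.0)),
            Atom(3, "CA", "C", "A", 3, "SER", (-3.0, 0.0, 0.0)),
            Atom(4, "CA", "C", "B", 1, "GLY", (0.0, 4.0, 0.0)),
        ]
        c = Complex(atoms)
        sel = interface_residues(c, 5.5)
        sets = {ps.name: ps for ps in residue_contact_counts(c, sel)}
        values = {cls: sets[f"contacts_{cls}_B"].points[0][1]
                  for cls in ("charged", "polar", "apolar")}
        assert values == {"charged": 2.0, "polar": 1.0, "apolar": 0.0}
        # each contact counted once per side: totals balance
        tot_a = sum(v for cls in ("charged", "polar", "apolar")
                    for _, v, _ in sets[f"contacts_{cls}_A"].points)
        tot_b = sum(v for cls in ("charged", "polar", "apolar")
                    for _, v, _ in sets[f"contacts_{cls}_B"].points)
        assert tot_a == tot_b == 3.0
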