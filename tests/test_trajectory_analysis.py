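"""Geometry operators against brute-force and analytic oracles."""

import itertools

import numpy as np
import pytest
import biotite.structure as bst

from conftest import make_trajectory
from corona_thermo import trajectory_analysis as ta
from corona_thermo.synthetic import (
    GeneratorSpec,
    gen_extended_chain,
    gen_ideal_helix,
    gen_toy_complex,
    gen_two_strand_sheet,
)


def _random_traj(rng, n_frames=3, n_atoms=50):
    coords = rng.normal(scale=8.0, size=(n_frames, n_atoms, 3))
    masses = rng.uniform(1.0, 20.0, n_atoms)
    return make_trajectory(coords, masses=masses)


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        t = make_trajectory(np.zeros((1, 1, 3)))
        _, mean, _ = ta.radius_of_gyration(t)
        assert mean == 0.0

    def test_cube_corners_give_sqrt3(self):
        pts = np.array(list(itertools.product([-1, 1], repeat=3)), float)
        _, mean, _ = ta.radius_of_gyration(make_trajectory(pts))
        assert mean == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        t = _random_traj(rng)
        rg, _, _ = ta.radius_of_gyration(t)
        for f in range(t.n_frames):
            m = t.masses
            com = (m[:, None] * t.coords[f]).sum(0) / m.sum()
            acc = sum(m[i] * np.dot(t.coords[f, i] - com, t.coords[f, i] - com)
                      for i in range(t.n_atoms))
            assert rg[f] == pytest.approx(np.sqrt(acc / m.sum()), abs=1e-10)

    def test_empty_selection_rejected(self, rng):
        t = _random_traj(rng)
        with pytest.raises(ta.SelectionError):
            ta.radius_of_gyration(t, np.zeros(t.n_atoms, dtype=bool))


class TestGyrationTensor:
    def test_collinear_points_have_two_zero_eigenvalues(self):
        pts = np.zeros((5, 3))
        pts[:, 0] = np.arange(5.0)
        g = ta.gyration_tensor(make_trajectory(pts))
        assert g.eigenvalues[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert g.eigenvalues[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert g.degenerate

    def test_trace_equals_rg_squared(self, rng):
        t = _random_traj(rng)
        g = ta.gyration_tensor(t)
        rg, _, _ = ta.radius_of_gyration(t)
        np.testing.assert_allclose(g.eigenvalues.sum(axis=1), rg ** 2,
                                   atol=1e-9)

    def test_uniform_sphere_semi_axes_close(self, rng):
        n = 10_000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = 30.0 * rng.uniform(size=n) ** (1 / 3)
        g = ta.gyration_tensor(make_trajectory(v * r[:, None]))
        np.testing.assert_allclose(g.semi_axes_mean, 30.0, rtol=0.02)

    def test_published_complex_axes_close_with_rg(self):
        # semi-axes (81.8, 80.2, 71.4 Å) and Rg 60.01 Å satisfy the
        # sqrt((a²+b²+c²)/5) closure within 1 %
        a, b, c = 81.8, 80.2, 71.4
        rg = np.sqrt((a * a + b * b + c * c) / 5.0)
        assert rg == pytest.approx(60.01, rel=0.01)


class TestContactFingerprint:
    def test_far_residue_has_zero_frequency(self):
        t = gen_toy_complex(GeneratorSpec(2), n_frames=4,
                            beads_per_protein=10)
        # push chain A far away so no residue can touch the micelle
        far = t.coords.copy()
        far[:, t.chain_ids == "A", :] += 500.0
        t2 = make_trajectory(far, masses=t.masses, chains=t.chain_ids,
                             res_ids=t.residue_indices,
                             res_names=t.residue_names,
                             charge=t.charge_class)
        fp = ta.contact_fingerprint(t2, ta.select(t2, chains="A"),
                                    ta.select(t2, chains="M"))
        assert np.all(fp.frequency == 0.0)

    def test_matches_all_pairs_brute_force(self, rng):
        coords = rng.normal(scale=6.0, size=(3, 60, 3))
        chains = np.r_[np.full(30, "P"), np.full(30, "M")]
        res_ids = np.r_[np.repeat(np.arange(1, 11), 3),
                        np.repeat(np.arange(1, 11), 3)]
        t = make_trajectory(coords, chains=chains, res_ids=res_ids)
        psel = ta.select(t, chains="P")
        msel = ta.select(t, chains="M")
        fp = ta.contact_fingerprint(t, psel, msel, cutoff=6.5)
        mic = np.flatnonzero(msel)
        for k, resid in enumerate(fp.residue_indices):
            atoms = np.flatnonzero(psel & (t.residue_indices == resid))
            hits = 0
            for f in range(3):
                dmin = min(np.linalg.norm(coords[f, i] - coords[f, j])
                           for i in atoms for j in mic)
                assert fp.min_distance[k, f] == pytest.approx(dmin, abs=1e-10)
                hits += dmin < 6.5
            assert fp.frequency[k] == pytest.approx(hits / 3)

    def test_rigid_motion_invariance(self, rng):
        t = gen_toy_complex(GeneratorSpec(5), planted=[(4, 0.5)], n_frames=4,
                            beads_per_protein=8)
        psel = ta.select(t, chains="A")
        msel = ta.select(t, chains="M")
        base = ta.contact_fingerprint(t, psel, msel).frequency
        # random rotation + translation applied per frame
        from scipy.spatial.transform import Rotation
        moved = t.coords.copy()
        for f in range(t.n_frames):
            rot = Rotation.random(random_state=f).as_matrix()
            moved[f] = moved[f] @ rot.T + rng.uniform(-50, 50, 3)
        t2 = make_trajectory(moved, masses=t.masses, chains=t.chain_ids,
                             res_ids=t.residue_indices,
                             res_names=t.residue_names,
                             charge=t.charge_class)
        after = ta.contact_fingerprint(t2, psel, msel).frequency
        np.testing.assert_allclose(after, base, atol=1e-12)

    def test_overlapping_selections_rejected(self, rng):
        t = _random_traj(rng)
        sel = np.ones(t.n_atoms, dtype=bool)
        with pytest.raises(ta.SelectionError):
            ta.contact_fingerprint(t, sel, sel)


class TestSaltBridges:
    def test_persistent_bridge_is_stable(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = 3.0  # always within 4 Å
        t = make_trajectory(coords, res_names=["CAT", "ANI"],
                            charge=["cationic", "anionic"],
                            chains=["M", "A"])
        sb = ta.salt_bridges(t, t.charge_class == "cationic",
                             t.charge_class == "anionic")
        assert sb.records[0].occupancy == 1.0 and sb.records[0].stable

    def test_fraction_stable_monotone_in_persistence(self):
        t = gen_toy_complex(GeneratorSpec(6),
                            planted=[(5, 0.9), (10, 0.6), (15, 0.3)],
                            n_frames=10)
        cat = ta.select(t, chains="M", charge="cationic")
        ani = ta.select(t, charge="anionic")
        fracs = [ta.salt_bridges(t, cat, ani, persistence=p)
                 .fraction_stable_cations for p in (0.2, 0.5, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_fraction_stable_monotone_in_distance_cutoff(self):
        t = gen_toy_complex(GeneratorSpec(6), planted=[(5, 0.9)], n_frames=6)
        cat = ta.select(t, chains="M", charge="cationic")
        ani = ta.select(t, charge="anionic")
        fracs = [ta.salt_bridges(t, cat, ani, dist_cutoff=d)
                 .fraction_stable_cations for d in (5.0, 4.0, 3.0, 2.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_wrong_charge_class_rejected(self, rng):
        t = _random_traj(rng)
        sel = np.ones(t.n_atoms, dtype=bool)
        with pytest.raises(ta.SelectionError):
            ta.salt_bridges(t, sel, sel)


class TestRDF:
    def test_fixed_distance_pair_lands_in_one_bin(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 1] = [10.0, 0, 0]
        coords[0, 2] = [0, 10.0, 0]
        t = make_trajectory(coords)
        ref = np.array([True, False, False])
        tgt = ~ref
        r = ta.rdf_from_com(t, ref, tgt, bin_width=1.0, r_max=20.0,
                            mode="counts")
        # distance exactly 10 Å falls in the right-open [10, 11) bin
        assert r.counts[(r.bin_centers > 10.0) & (r.bin_centers < 11.0)] == 2.0
        assert r.counts.sum() == 2.0

    def test_uniform_gas_has_flat_g(self, rng):
        # points uniform in a box, COM reference, density given explicitly
        L = 100.0
        n = 40_000
        coords = rng.uniform(-L / 2, L / 2, size=(1, n, 3))
        t = make_trajectory(coords)
        ref = np.ones(n, dtype=bool)      # COM of everything = box centre
        tgt = np.zeros(n, dtype=bool)
        tgt[1:] = True
        r = ta.rdf_from_com(t, ref, tgt, bin_width=2.0, r_max=50.0,
                            number_density=n / L ** 3)
        sel = (r.bin_centers > 5.0) & (r.bin_centers < 25.0)
        counts = r.counts[sel]
        sigma = np.sqrt(counts) / np.maximum(counts, 1)
        assert np.all(np.abs(r.g[sel] - 1.0) <= 3.0 * sigma + 0.05)

    def test_protein_shell_sits_in_head_region(self):
        t = gen_toy_complex(GeneratorSpec(9), n_frames=5)
        mic = ta.select(t, chains="M")
        prot = ~mic
        r = ta.rdf_from_com(t, mic, prot, bin_width=1.0, r_max=60.0,
                            mode="counts")
        shell = (r.bin_centers >= 35.0) & (r.bin_centers <= 45.0)
        assert r.counts[shell].sum() / r.counts.sum() >= 0.95

    def test_empty_target_flagged(self, rng):
        t = _random_traj(rng)
        ref = np.ones(t.n_atoms, dtype=bool)
        r = ta.rdf_from_com(t, ref, np.zeros(t.n_atoms, dtype=bool))
        assert r.empty and np.all(r.g == 0.0)


class TestSASA:
    def test_single_atom_closed_form(self):
        t = make_trajectory(np.zeros((1, 1, 3)))
        s = ta.sasa(t, radii=np.array([1.6]))
        assert s.total == pytest.approx(4 * np.pi * 3.0 ** 2, rel=1e-12)

    def test_two_spheres_match_cap_formula(self):
        for d in (2.0, 3.0, 4.0, 5.0):
            coords = np.zeros((1, 2, 3))
            coords[0, 1, 0] = d
            t = make_trajectory(coords)
            s = ta.sasa(t, radii=np.array([1.6, 1.8]))
            r1, r2 = 1.6 + 1.4, 1.8 + 1.4
            total = 0.0
            for ra, rb in ((r1, r2), (r2, r1)):
                cap_h = ra - (d * d + ra * ra - rb * rb) / (2 * d)
                buried = 2 * np.pi * ra * max(cap_h, 0.0)
                total += 4 * np.pi * ra * ra - buried
            assert s.total == pytest.approx(total, rel=0.02)

    def test_fully_buried_atom_zero(self):
        # central atom enclosed by 12 neighbours on an icosahedral shell
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array([(0, 1, phi), (0, -1, phi), (0, 1, -phi),
                          (0, -1, -phi), (1, phi, 0), (-1, phi, 0),
                          (1, -phi, 0), (-1, -phi, 0), (phi, 0, 1),
                          (-phi, 0, 1), (phi, 0, -1), (-phi, 0, -1)], float)
        verts *= 2.0 / np.linalg.norm(verts[0])
        coords = np.vstack([np.zeros(3), verts])[None, :, :]
        t = make_trajectory(coords)
        s = ta.sasa(t, radii=np.r_[1.5, np.full(12, 2.0)])
        assert s.per_atom[0] == 0.0

    def test_rotation_translation_invariance(self, rng):
        coords = rng.normal(scale=4.0, size=(1, 30, 3))
        t = make_trajectory(coords)
        base = ta.sasa(t).total
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=1).as_matrix()
        t2 = make_trajectory(coords @ rot.T + 20.0)
        assert ta.sasa(t2).total == pytest.approx(base, rel=0.005)

    def test_matches_independent_implementation(self, rng):
        # cross-check against biotite's Shrake-Rupley on a random cluster
        coords = rng.normal(scale=5.0, size=(1, 25, 3)).astype(np.float32)
        arr = bst.AtomArray(25)
        arr.coord = coords[0]
        arr.element = np.full(25, "C")
        arr.atom_name = np.full(25, "C")
        arr.res_name = np.full(25, "UNK")
        arr.res_id = np.arange(1, 26)
        arr.chain_id = np.full(25, "A")
        # biotite's "Single" radii set assigns carbon the same 1.7 Å
        ref = bst.sasa(arr, probe_radius=1.4, point_number=1000,
                       vdw_radii="Single").sum()
        t = make_trajectory(coords.astype(float))
        got = ta.sasa(t, radii=np.full(25, 1.7)).total
        assert got == pytest.approx(ref, rel=0.02)

    def test_unknown_radius_names_atom(self):
        t = make_trajectory(np.zeros((1, 1, 3)), elements=["XX"],
                            names=["QQ"])
        with pytest.raises(ValueError, match="QQ"):
            ta.sasa(t)

    def test_total_is_sum_of_residues(self, rng):
        t = _random_traj(rng, n_frames=1, n_atoms=20)
        s = ta.sasa(t, radii=np.full(20, 1.7))
        assert s.total == pytest.approx(sum(s.per_residue.values()), abs=1e-6)


class TestStoichiometry:
    def test_published_areas_give_six_to_one(self):
        ratio, nearest = ta.stoichiometry_estimate(35618.0, 5835.0)
        assert round(ratio, 1) == 6.1 and nearest == 6

    def test_equal_areas(self):
        ratio, nearest = ta.stoichiometry_estimate(100.0, 100.0)
        assert ratio == 1.0 and nearest == 1

    def test_scale_invariance(self):
        r1, _ = ta.stoichiometry_estimate(35618.0, 5835.0)
        r2, _ = ta.stoichiometry_estimate(3.5618, 0.5835)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_patch_rejected(self):
        with pytest.raises(ValueError):
            ta.stoichiometry_estimate(100.0, 0.0)


class TestSecondaryStructure:
    def test_ideal_helix_interior_mostly_h(self):
        labels, _ = ta.assign_secondary_structure(gen_ideal_helix(20))
        interior = [labels[("A", i)] for i in range(3, 18)]
        assert interior.count("H") / len(interior) >= 0.8

    def test_hand_checked_hbond_energy(self):
        # ideal helix: the i -> i+4 backbone bond energy recomputed by hand
        t = gen_ideal_helix(8)
        bonds, keys, _ = ta.kabsch_sander_hbonds(t)
        assert (1, 5) in bonds  # acceptor residue 2, donor residue 6
        coords = {(int(r), n): t.coords[0, i]
                  for i, (n, r) in enumerate(zip(t.atom_names,
                                                 t.residue_indices))}
        c, o = coords[(2, "C")], coords[(2, "O")]
        n6 = coords[(6, "N")]
        co = coords[(5, "C")] - coords[(5, "O")]
        h = n6 + co / np.linalg.norm(co)
        e = 0.084 * 332 * (1 / np.linalg.norm(o - n6)
                           + 1 / np.linalg.norm(c - h)
                           - 1 / np.linalg.norm(o - h)
                           - 1 / np.linalg.norm(c - n6))
        assert e < -0.5

    def test_extended_chain_has_no_helix_or_strand(self):
        _, fr = ta.assign_secondary_structure(gen_extended_chain(12))
        assert fr["H"] == 0.0 and fr["E"] == 0.0

    def test_parallel_strand_pair_forms_ladder(self):
        labels, fr = ta.assign_secondary_structure(gen_two_strand_sheet(8))
        assert fr["E"] > 0.0
        interior_a = [labels[("A", i)] for i in range(3, 7)]
        assert "E" in interior_a

    def test_missing_backbone_labelled_coil(self):
        t = gen_ideal_helix(10)
        keep = ~((t.residue_indices == 5) & (t.atom_names == "O"))
        t2 = make_trajectory(t.coords[:, keep, :], chains=t.chain_ids[keep],
                             res_ids=t.residue_indices[keep],
                             names=t.atom_names[keep],
                             elements=t.elements[keep])
        labels, _ = ta.assign_secondary_structure(t2)
        assert labels[("A", 5)] in "CTH"  # never crashes; residue downgraded


class TestFramePermutationInvariance:
    def test_fingerprint_and_bridges_order_independent(self):
        t = gen_toy_complex(GeneratorSpec(12), planted=[(5, 0.5)], n_frames=6,
                            beads_per_protein=8)
        perm = np.array([3, 0, 5, 1, 4, 2])
        t2 = make_trajectory(t.coords[perm], masses=t.masses,
                             chains=t.chain_ids, res_ids=t.residue_indices,
                             res_names=t.residue_names, charge=t.charge_class)
        psel = ta.select(t, chains="A")
        msel = ta.select(t, chains="M")
        np.testing.assert_array_equal(
            ta.contact_fingerprint(t, psel, msel).frequency,
            ta.contact_fingerprint(t2, psel, msel).frequency)
        cat = ta.select(t, chains="M", charge="cationic")
        ani = ta.select(t, charge="anionic")
        assert (ta.salt_bridges(t, cat, ani).fraction_stable_cations
                == ta.salt_bridges(t2, cat, ani).fraction_stable_cations)
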