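"""Parametric building, threading, mutation, superposition, relaxation."""

import numpy as np
import pytest

from alazip.records import ProteinRecord
from alazip.coilbuild import (HEPTAD_TWIST, HelixParams, ThreadingMap,
                              build_dimer, build_ideal_helix, interface_phase,
                              mutate_core, relax_sidechains,
                              superpose_and_rmsd, thread_sequence)
from alazip.seqmotif import assign_heptads
from alazip.structure import Atom, Chain, Residue, Structure3D, make_tip_atom
from alazip.synthetic import ZipperSpec, generate_dimer_fixture

from conftest import rigid_transform


class TestBuildIdealHelix:
    def test_ca_ca_distance_near_canonical(self):
        # geometry oracle: chord = sqrt((2 r sin(t/2))^2 + rise^2)
        for params in (HelixParams(), HelixParams.heptad_locked()):
            h = build_ideal_helix("A" * 18, params)
            ca = h.coords(atom_names={"CA"})
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            t = np.radians(params.twist_per_residue)
            expected = np.hypot(2 * params.helix_radius * np.sin(t / 2),
                                params.rise_per_residue)
            assert np.allclose(d, expected)
            assert np.all(np.abs(d - 3.8) <= 0.1)

    def test_axial_rise(self):
        h = build_ideal_helix("A" * 18)
        ca = h.coords(atom_names={"CA"})
        assert ca[-1, 2] - ca[0, 2] == pytest.approx(17 * 1.5)

    def test_single_residue(self):
        h = build_ideal_helix("K")
        res = h.chains[0].residues[0]
        assert {a.name for a in res.atoms} == {"N", "CA", "C", "O", "CB",
                                               "TIP"}
        assert res.atom("TIP").charge == 1.0

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError):
            build_ideal_helix("AB")

    def test_tip_lengths_match_table(self):
        h = build_ideal_helix("DEKRA")
        for res, expected in zip(h.chains[0].residues,
                                 (3.7, 5.0, 6.4, 7.3, 1.5)):
            d = np.linalg.norm(res.atom("TIP").xyz - res.atom("CA").xyz)
            assert d == pytest.approx(expected)


class TestThreading:
    def test_native_map_pairs_45_residues(self):
        template = build_ideal_helix("L" * 45, HelixParams.heptad_locked(),
                                     start_index=278)
        query = ProteinRecord("q", "A" * 100)
        tmap = ThreadingMap(query_span=(37, 81), template_span=(278, 322))
        assert tmap.n_pairs == 45
        out = thread_sequence(query, template, tmap)
        assert len(out.chains[0].residues) == 45
        assert out.chains[0].residues[0].index == 37
        assert out.chains[0].residues[-1].index == 81

    def test_backbone_preserved_bit_for_bit(self):
        template = build_ideal_helix("LEKARND" * 4)
        query = ProteinRecord("q", "ADKLERS" * 4)
        out = thread_sequence(query, template,
                              ThreadingMap((1, 28), (1, 28)))
        sel = ("N", "CA", "C", "O")
        tb = template.coords(atom_names=set(sel))
        ob = out.coords(atom_names=set(sel))
        assert np.array_equal(tb, ob)

    def test_self_threading_rmsd_zero(self):
        record = ProteinRecord("q", "ADKLERS" * 3)
        template = build_ideal_helix(record)
        out = thread_sequence(record, template, ThreadingMap((1, 21), (1, 21)))
        rmsd, _ = superpose_and_rmsd(template, out)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_register_shift_semantics(self):
        """Under the 'd' convention, a -1 offset puts the core at 'c'
        and the +3 presentation puts it at 'a' (checked on labels)."""
        # template register: position 4 is 'd' (core), heptads start at 'a'
        record = ProteinRecord("q", "X" * 42)
        core_positions = [4, 11, 18, 25, 32, 39]
        asg = assign_heptads(record, (1, 42), 0)
        assert all(asg.label(p) == "d" for p in core_positions)
        # sliding the sequence one register position moves each core to
        # template position core-1, labelled 'c'
        assert all(asg.label(p - 1) == "c" for p in core_positions)
        # the three-position slide continues d -> c -> b -> 'a'
        assert all(asg.label(p - 3) == "a" for p in core_positions)

    def test_bpc6_shifted_template_span_has_41_pairs(self):
        tmap = ThreadingMap(query_span=(37, 77), template_span=(268, 308),
                            offset=-1)
        assert tmap.n_pairs == 41

    def test_span_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ThreadingMap(query_span=(1, 10), template_span=(1, 11))


class TestMutateCore:
    def test_core_swap_preserves_backbone(self, parallel_dimer):
        dimer, info = parallel_dimer
        core = info["zipper"].core_positions
        swapped = mutate_core(dimer, "A", "L", core)
        rmsd, _ = superpose_and_rmsd(dimer, swapped)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        for ch in swapped.chains:
            for pos in core:
                assert ch.residue(pos).name == "LEU"

    def test_empty_positions_is_identity(self):
        h = build_ideal_helix("AAAA")
        out = mutate_core(h, "A", "L", [])
        assert np.array_equal(h.coords(), out.coords())

    def test_round_trip_restores_original(self):
        h = build_ideal_helix("AKEAD")
        back = mutate_core(mutate_core(h, "A", "L", [1, 4]), "L", "A", [1, 4])
        assert np.allclose(h.coords(), back.coords(), atol=1e-12)
        assert [r.name for r in back.chains[0].residues] == \
            [r.name for r in h.chains[0].residues]

    def test_wrong_source_residue_raises(self):
        h = build_ideal_helix("AKEAD")
        with pytest.raises(ValueError):
            mutate_core(h, "A", "L", [2])


class TestSuperposition:
    def test_identity_gives_zero(self):
        h = build_ideal_helix("ADKLE")
        rmsd, _ = superpose_and_rmsd(h, h.copy())
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_known_rigid_motion_recovered(self):
        rng = np.random.default_rng(3)
        a = build_ideal_helix("ADKLERS" * 3)
        b = a.copy()
        rot, t = rigid_transform(rng)
        b.transform(rot, t)
        rmsd, (r_est, t_est) = superpose_and_rmsd(a, b)
        assert rmsd < 1e-6
        # the recovered transform must invert the applied one
        assert np.allclose(r_est @ rot, np.eye(3), atol=1e-9)

    def test_three_point_toy_matches_grid_search_oracle(self):
        delta = 0.9

        def toy(points):
            residues = [Residue(i + 1, "GLY", [Atom("CA", "C", p)])
                        for i, p in enumerate(points)]
            return Structure3D([Chain("A", residues)])

        a = toy([(-1, 0, 0), (0, 0, 0), (1, 0, 0)])
        b = toy([(-1, 0, 0), (0, delta, 0), (1, 0, 0)])
        rmsd, _ = superpose_and_rmsd(a, b, atom_selection="CA")
        # independent oracle: exhaustive in-plane rotation search after
        # centering (the optimal rotation is in the xy-plane by symmetry)
        pa = np.array([(-1, 0), (0, 0), (1, 0)], float)
        pb = np.array([(-1, -delta / 3), (0, 2 * delta / 3),
                       (1, -delta / 3)], float)
        best = np.inf
        for theta in np.linspace(0, 2 * np.pi, 100001):
            c, s = np.cos(theta), np.sin(theta)
            rotated = pb @ np.array([[c, s], [-s, c]])
            best = min(best, np.sqrt(np.mean(np.sum((rotated - pa) ** 2,
                                                    axis=1))))
        assert rmsd == pytest.approx(best, abs=1e-6)
        assert rmsd == pytest.approx(delta * np.sqrt(2) / 3, abs=1e-6)

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            superpose_and_rmsd(build_ideal_helix("ADK"),
                               build_ideal_helix("ADKL"))

    def test_agrees_with_independent_library_superposition(self):
        import biotite.structure as bst
        rng = np.random.default_rng(8)
        a = build_ideal_helix("ADKLERSNQ")
        b = a.copy()
        rot, t = rigid_transform(rng)
        b.transform(rot, t)
        # perturb b so the optimum is nontrivial
        for _, _, atom in b.iter_atoms():
            atom.xyz = atom.xyz + rng.normal(scale=0.3, size=3)
        rmsd, _ = superpose_and_rmsd(a, b, atom_selection="all")
        fitted, _ = bst.superimpose(a.to_atom_array(), b.to_atom_array())
        ref = float(bst.rmsd(a.to_atom_array(), fitted))
        assert rmsd == pytest.approx(ref, abs=1e-6)


class TestBuildDimer:
    def test_parallel_construction_places_salt_bridge_partners(
            self, parallel_dimer):
        """Every complementary heptad's Glu('g') tip on one chain lies
        within the salt-bridge cutoff of the next heptad's Lys('a') tip
        on the facing chain."""
        dimer, info = parallel_dimer
        a, b = dimer.chains
        for (pa, pb) in info["expected_salt_bridges"]:
            tip_a = a.residue(pa).atom("TIP").xyz
            tip_b = b.residue(pb).atom("TIP").xyz
            assert np.linalg.norm(tip_a - tip_b) <= 4.0

    def test_antiparallel_ends_meet(self):
        dimer, _ = generate_dimer_fixture(ZipperSpec(seed=9),
                                          orientation="antiparallel")
        a, b = dimer.chains
        z_a = np.array([r.atom("CA").xyz[2] for r in a.residues])
        z_b = np.array([r.atom("CA").xyz[2] for r in b.residues])
        # chain B runs N->C against chain A; its first residue is axially
        # aligned with chain A's last residue
        assert np.all(np.diff(z_a) > 0) and np.all(np.diff(z_b) < 0)
        assert int(np.argmin(np.abs(z_a - z_b[0]))) == len(a.residues) - 1

    def test_huge_separation_kills_contacts(self):
        from alazip.interactions import interface_inventory
        dimer, _ = generate_dimer_fixture(ZipperSpec(seed=9),
                                          separation=100.0)
        inv = interface_inventory(dimer)
        assert inv.n_salt_bridges == 0 and inv.n_hbonds == 0

    def test_interface_phase_is_heptad_periodic(self):
        assert interface_phase(0) == pytest.approx(180.0 / 7.0)
        assert (interface_phase(7) - interface_phase(0)) % 360 \
            == pytest.approx(0.0)
        assert interface_phase(3) - interface_phase(0) \
            == pytest.approx(3 * HEPTAD_TWIST)


class TestRelaxSidechains:
    def test_zero_steps_is_identity(self, parallel_dimer):
        dimer, _ = parallel_dimer
        out = relax_sidechains(dimer, n_steps=0)
        assert np.array_equal(dimer.coords(), out.coords())

    def test_overlapping_tips_separate(self):
        # two Lys tips overlapping off-axis (radii 2.0 + 2.0 > distance)
        def res(idx, ca, tip):
            return Residue(idx, "LYS", [Atom("CA", "C", ca),
                                        Atom("CB", "C", np.add(ca, (1.5, 0, 0))),
                                        make_tip_atom("LYS", tip)])

        s = Structure3D([
            Chain("A", [res(1, (0, 0, 0), (6.0, 1.0, 0))]),
            Chain("B", [res(1, (12.0, 0, 0), (6.8, -1.0, 0.5))]),
        ])
        d0 = np.linalg.norm(np.subtract((6.0, 1.0, 0), (6.8, -1.0, 0.5)))
        assert d0 < 4.0
        out, trace = relax_sidechains(s, n_steps=100, return_trace=True)
        tips = [a.xyz for _, _, a in out.iter_atoms() if a.name == "TIP"]
        assert np.linalg.norm(tips[0] - tips[1]) > d0
        assert trace[-1] < trace[0]

    def test_energy_trace_monotone_on_dimer(self, parallel_dimer):
        dimer, _ = parallel_dimer
        _, trace = relax_sidechains(dimer, n_steps=200, return_trace=True)
        diffs = np.diff(np.array(trace))
        assert np.all(diffs <= 1e-12)

    def test_bond_lengths_preserved(self, parallel_dimer):
        dimer, _ = parallel_dimer
        out = relax_sidechains(dimer, n_steps=50)
        for (ch0, ch1) in zip(dimer.chains, out.chains):
            for (r0, r1) in zip(ch0.residues, ch1.residues):
                b0 = np.linalg.norm(r0.atom("TIP").xyz - r0.atom("CA").xyz)
                b1 = np.linalg.norm(r1.atom("TIP").xyz - r1.atom("CA").xyz)
                assert b1 == pytest.approx(b0, abs=1e-9)
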