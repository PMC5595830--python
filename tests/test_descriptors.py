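import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actiflow.descriptors import (
    FINGERPRINT_BITS,
    build_descriptor_set,
    compute_features,
    compute_fingerprint,
    detect_hbond,
    pair_distance,
    segment_rmsd,
)
from actiflow.synthetic import (
    MultiWellSpec,
    ToyComplexSpec,
    build_toy_complex,
    embed_latent_as_distance,
    linear_chain_structure,
    simulate_multiwell,
)
from actiflow.trajio import MolecularStructure, ResidueSelection, TrajectoryEnsemble


def make_structure(atoms):
    """atoms: list of (resid, resname, name, element, xyz)."""
    n = len(atoms)
    return MolecularStructure(
        serial=np.arange(1, n + 1),
        name=np.array([a[2] for a in atoms], dtype="U6"),
        element=np.array([a[3] for a in atoms], dtype="U2"),
        resid=np.array([a[0] for a in atoms], dtype=int),
        resname=np.array([a[1] for a in atoms], dtype="U6"),
        chain=np.array(["A"] * n, dtype="U4"),
        is_ligand=np.zeros(n, dtype=bool),
        xyz=np.array([a[4] for a in atoms], dtype=float),
    )


def as_ensemble(structure, frames=None):
    frames = structure.xyz[None] if frames is None else frames
    return TrajectoryEnsemble(topology=structure, frames=[frames], frame_interval_ns=1.0)


class TestBuildDescriptorSet:
    def test_97_residue_selection_gives_4656_pairs(self):
        top = linear_chain_structure(60, 360, with_ligand=True)
        sel = ResidueSelection(tuple(range(64, 353, 3)))
        assert len(sel) == 97
        dset = build_descriptor_set(top, sel, ligand_range=(64, 352))
        assert dset.count("ca_pair_distance") == 4656
        assert dset.count("ligand_contact") == 289

    @given(n=st.integers(2, 25))
    @settings(max_examples=20, deadline=None)
    def test_pair_count_identity(self, n):
        top = linear_chain_structure(1, 30)
        sel = ResidueSelection(tuple(range(1, n + 1)))
        dset = build_descriptor_set(top, sel)
        assert dset.count("ca_pair_distance") == n * (n - 1) // 2

    def test_sidechain_contacts_discovered_from_reference(self):
        # residues 1-2 sidechains at 5 A; residue 3 far away
        ref = make_structure([
            (1, "SER", "CA", "C", (0, 0, 0)), (1, "SER", "CB", "C", (1.5, 0, 0)),
            (2, "SER", "CA", "C", (8, 0, 0)), (2, "SER", "CB", "C", (6.5, 0, 0)),
            (3, "SER", "CA", "C", (30, 0, 0)), (3, "SER", "CB", "C", (31.5, 0, 0)),
        ])
        dset = build_descriptor_set(ref, ResidueSelection((1, 2, 3)), reference_structures=[ref])
        contacts = [d for d in dset.descriptors if d.kind == "sidechain_contact"]
        assert [(d.res_a, d.res_b) for d in contacts] == [(1, 2)]

    def test_empty_selection_rejected(self):
        top = linear_chain_structure(1, 5)
        with pytest.raises(ValueError):
            build_descriptor_set(top, ResidueSelection(()))


class TestComputeFeatures:
    def test_ca_distance_value(self):
        s = make_structure([
            (1, "GLY", "CA", "C", (0, 0, 0)),
            (2, "GLY", "CA", "C", (5, 0, 0)),
        ])
        dset = build_descriptor_set(s, ResidueSelection((1, 2)))
        fm = compute_features(as_ensemble(s), dset)
        assert fm.blocks[0][0, 0] == pytest.approx(5.0)

    @pytest.mark.parametrize("d,expected", [(6.9, 1.0), (7.1, 0.0)])
    def test_contact_cutoff_is_strict(self, d, expected):
        ref = make_structure([
            (1, "SER", "CA", "C", (0, 0, 0)), (1, "SER", "CB", "C", (0, 0, 0)),
            (2, "SER", "CA", "C", (5, 0, 0)), (2, "SER", "CB", "C", (5, 0, 0)),
        ])
        s = make_structure([
            (1, "SER", "CA", "C", (0, 0, 0)), (1, "SER", "CB", "C", (0, 0, 0)),
            (2, "SER", "CA", "C", (d, 0, 0)), (2, "SER", "CB", "C", (d, 0, 0)),
        ])
        dset = build_descriptor_set(ref, ResidueSelection((1, 2)), reference_structures=[ref])
        fm = compute_features(as_ensemble(s), dset)
        contact_col = fm.names.index("scc_1_2")
        assert fm.blocks[0][0, contact_col] == expected

    def test_contacts_invariant_under_rigid_motion(self):
        ref = make_structure([
            (1, "SER", "CA", "C", (0, 0, 0)), (1, "SER", "CB", "C", (1, 0, 0)),
            (2, "SER", "CA", "C", (5, 0, 0)), (2, "SER", "CB", "C", (4, 0, 0)),
        ])
        dset = build_descriptor_set(ref, ResidueSelection((1, 2)), reference_structures=[ref])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = make_structure([
            (1, "SER", "CA", "C", (0, 0, 0)), (1, "SER", "CB", "C", (0, 0, 0)),
            (2, "SER", "CA", "C", (0, 0, 0)), (2, "SER", "CB", "C", (0, 0, 0)),
        ])
        moved.xyz = ref.xyz @ R.T + np.array([10.0, -3.0, 7.0])
        f_ref = compute_features(as_ensemble(ref), dset).blocks[0]
        f_mov = compute_features(as_ensemble(moved), dset).blocks[0]
        np.testing.assert_allclose(f_ref, f_mov, atol=1e-9)

    def test_multiwell_embedding_recovers_affine_latent(self):
        latent = simulate_multiwell(MultiWellSpec(
            centers=[-1, 1], depths=[2, 2], widths=0.5, confinement=0.5,
            n_frames=300, seed=11, dt=0.01,
        ))
        ens = embed_latent_as_distance(latent, offset=12.0, scale=1.5)
        dset = build_descriptor_set(ens.topology, ResidueSelection((1, 2)))
        fm = compute_features(ens, dset)
        np.testing.assert_allclose(fm.blocks[0][:, 0], 12.0 + 1.5 * latent, atol=1e-9)

    def test_missing_atoms_error_names_descriptor(self):
        top = linear_chain_structure(1, 3)  # no ligand
        dset = build_descriptor_set(top, ResidueSelection((1, 2)), ligand_range=(1, 3))
        with pytest.raises(KeyError, match="lig_1"):
            compute_features(as_ensemble(top), dset)


class TestSegmentRmsd:
    def make_six_atom_system(self):
        atoms = [(i, "GLY", "CA", "C", (3.8 * i, 0, 0)) for i in range(1, 13)]
        return make_structure(atoms)

    def test_reference_vs_itself_is_zero(self):
        s = self.make_six_atom_system()
        trace = segment_rmsd(as_ensemble(s), s, segment=(4, 9))
        assert trace.stacked[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_translation_is_zero_after_fit(self):
        s = self.make_six_atom_system()
        frames = (s.xyz + np.array([5.0, -2.0, 9.0]))[None]
        trace = segment_rmsd(as_ensemble(s, frames), s, segment=(4, 9))
        assert trace.stacked[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_segment_atom(self):
        # one of six segment atoms moved by 0.6 A perpendicular to the chain,
        # fit restricted to untouched residues -> RMSD = 0.6 / sqrt(6)
        s = self.make_six_atom_system()
        frames = s.xyz.copy()
        seg_res = list(range(4, 10))
        moved_idx = s.ca_index(6)
        frames[moved_idx, 1] += 0.6
        fit = ResidueSelection(tuple(r for r in range(1, 13) if r not in seg_res))
        trace = segment_rmsd(as_ensemble(s, frames[None]), s, segment=(4, 9), fit_selection=fit)
        assert trace.stacked[0] == pytest.approx(0.6 / np.sqrt(6), abs=1e-9)


class TestPairDistance:
    def test_coincident_atoms_zero(self):
        s = make_structure([
            (1, "GLY", "CA", "C", (1, 1, 1)),
            (2, "GLY", "CA", "C", (1, 1, 1)),
        ])
        assert pair_distance(s, 1, 2, "ca").stacked[0] == 0.0

    def test_min_sidechain_hand_computed(self):
        s = make_structure([
            (1, "SER", "CA", "C", (0, 0, 0)), (1, "SER", "CB", "C", (1, 0, 0)),
            (1, "SER", "OG", "O", (2, 0, 0)),
            (2, "SER", "CA", "C", (9, 0, 0)), (2, "SER", "CB", "C", (5.0, 1.1, 0)),
            (2, "SER", "OG", "O", (7, 0, 0)),
        ])
        # nearest sidechain pair: CB(1) at (1,0,0) vs CB(2) at (5.0,1.1,0)?
        # no: OG(1) at (2,0,0) vs CB(2): sqrt(3.0^2 + 1.1^2) = 3.195...;
        # crafted nearest pair OG(1)-CB(2) hand-computed below
        expected = np.hypot(3.0, 1.1)
        assert pair_distance(s, 1, 2, "min_sidechain").stacked[0] == pytest.approx(expected, abs=1e-9)

    def test_crystal_fragment_pocket_distances(self, inactive_fragment, active_fragment):
        d_in = pair_distance(inactive_fragment, 240, 297, "min_sidechain").stacked[0]
        d_act = pair_distance(active_fragment, 240, 297, "min_sidechain").stacked[0]
        assert d_in == pytest.approx(4.4, abs=0.05)
        assert d_act == pytest.approx(4.0, abs=0.05)

    def test_fragment_contains_activation_marker_residues(self, inactive_fragment):
        present = set(int(r) for r in inactive_fragment.residue_numbers())
        assert {165, 279, 240, 297}.issubset(present)
        d = pair_distance(inactive_fragment, 165, 279, "ca").stacked[0]
        assert d < 10.0  # TM6 closed in the inactive fragment


class TestDetectHbond:
    def build_pair(self, distance, with_h=False, angle=180.0):
        atoms = [
            (1, "SER", "CA", "C", (-2, 0, 0)), (1, "SER", "CB", "C", (-1, 0, 0)),
            (1, "SER", "OG", "O", (0, 0, 0)),
            (2, "ASP", "CA", "C", (distance + 2, 0, 0)), (2, "ASP", "CB", "C", (distance + 1, 0, 0)),
            (2, "ASP", "OD1", "O", (distance, 0, 0)),
        ]
        if with_h:
            # hydrogen 1.0 A from OG; D-H...A angle controlled by placement
            theta = np.radians(180.0 - angle)
            h_pos = (np.cos(theta), np.sin(theta), 0)
            atoms.insert(3, (1, "SER", "HG", "H", h_pos))
        return make_structure(atoms)

    def test_close_near_linear_geometry_forms_bond(self):
        s = self.build_pair(2.9, with_h=True, angle=175.0)
        assert detect_hbond(s, 1, 2).stacked[0] == 1.0

    def test_far_apart_is_broken(self):
        assert detect_hbond(self.build_pair(5.0), 1, 2).stacked[0] == 0.0

    def test_bent_geometry_fails_angle_term(self):
        s = self.build_pair(3.4, with_h=True, angle=100.0)
        assert detect_hbond(s, 1, 2).stacked[0] == 0.0

    def test_no_donor_atoms_raises(self):
        s = make_structure([
            (1, "ALA", "CA", "C", (0, 0, 0)), (1, "ALA", "CB", "C", (1, 0, 0)),
            (2, "ASP", "CA", "C", (4, 0, 0)), (2, "ASP", "OD1", "O", (3, 0, 0)),
        ])
        with pytest.raises(KeyError, match="donor"):
            detect_hbond(s, 1, 2)


class TestFingerprint:
    @pytest.mark.parametrize(
        "archetype,on,off",
        [
            ("apolar", 4.4, 4.6),
            ("aromatic_face", 3.8, 4.2),
            ("aromatic_edge", 3.8, 4.2),
            ("hbond_donor", 2.9, 3.7),
            ("hbond_acceptor", 2.9, 3.7),
            ("electrostatic_positive", 3.8, 4.2),
            ("electrostatic_negative", 3.8, 4.2),
        ],
    )
    def test_each_bit_switches_at_its_cutoff(self, archetype, on, off):
        for d, expected in [(on, 1), (off, 0)]:
            structure, typing = build_toy_complex(ToyComplexSpec([(archetype, d)]))
            fp = compute_fingerprint(structure, typing)
            assert int(fp[archetype].sum()) == expected
            assert int(fp.values.sum()) == expected  # no other bit leaks

    def test_all_seven_archetypes_set_exactly_their_bits(self, full_toy_complex):
        structure, typing = full_toy_complex
        fp = compute_fingerprint(structure, typing)
        assert fp.shape == (7, 7)
        np.testing.assert_array_equal(np.diag(fp.values), np.ones(7, dtype=int))
        assert fp.values.sum() == 7

    def test_unknown_residue_warns_and_zeroes(self):
        structure, typing = build_toy_complex(ToyComplexSpec([("apolar", 4.0)]))
        structure.resname[structure.resname == "LEU"] = "XYZ"
        with pytest.warns(UserWarning, match="unknown type"):
            fp = compute_fingerprint(structure, typing)
        assert fp.values.sum() == 0

    def test_bit_order_is_fixed(self, full_toy_complex):
        structure, typing = full_toy_complex
        assert tuple(compute_fingerprint(structure, typing).columns) == FINGERPRINT_BITS
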