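"""Structural metrics on toy frames: distances, centers of mass, hydrogen
bonds, RMSF and helix angles, plus file round-trips and rigid invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import smfretkit as sk
from smfretkit import structures as st

from conftest import ideal_helix


def random_rigid(seed):
    rot = Rotation.random(random_state=seed).as_matrix()
    trans = np.random.default_rng(seed).uniform(-20, 20, 3)
    return rot, trans


class TestPairDistance:
    SPEC = st.ResiduePairSpec("LBD-LBD", "A", 248, "B", 248)

    def test_constructed_distance(self, toy_pair_frame):
        assert st.pair_distance(toy_pair_frame, self.SPEC) \
            == pytest.approx(38.2)

    def test_coincident_atoms_zero(self):
        atoms = [("A", 1, "GLY", "CA", "C", (1.0, 1.0, 1.0)),
                 ("B", 1, "GLY", "CA", "C", (1.0, 1.0, 1.0))]
        frame = sk.make_toy_frames(atoms)[0]
        spec = st.ResiduePairSpec("x", "A", 1, "B", 1)
        assert st.pair_distance(frame, spec) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_invariance(self, toy_pair_frame, seed):
        rot, trans = random_rigid(seed)
        moved = toy_pair_frame.transformed(rot, trans)
        assert st.pair_distance(moved, self.SPEC) \
            == pytest.approx(st.pair_distance(toy_pair_frame, self.SPEC))

    def test_missing_residue_named_in_error(self, toy_pair_frame):
        spec = st.ResiduePairSpec("x", "A", 999, "B", 248)
        with pytest.raises(KeyError, match="999"):
            st.pair_distance(toy_pair_frame, spec)


class TestClamshellDistance:
    def frame(self):
        atoms = [("A", 144, "TYR", "CA", "C", (0.0, 0.0, 0.0)),
                 ("A", 272, "SER", "CA", "C", (0.0, 24.0, 0.0))]
        return sk.make_toy_frames(atoms)[0]

    def test_constructed_value_and_invariance(self):
        frame = self.frame()
        assert st.clamshell_distance(frame, "A") == pytest.approx(24.0)
        rot, trans = random_rigid(5)
        assert st.clamshell_distance(frame.transformed(rot, trans), "A") \
            == pytest.approx(24.0)


class TestLobeSeparation:
    def two_clouds(self, sep=57.0, n=25, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 3, (n, 3))
        a -= a.mean(axis=0)
        b = rng.normal(0, 3, (n, 3))
        b -= b.mean(axis=0)
        b += np.array([sep, 0.0, 0.0])
        atoms = [("A", 190 + i, "GLY", "CA", "C", tuple(a[i]))
                 for i in range(n)]
        atoms += [("B", 190 + i, "GLY", "CA", "C", tuple(b[i]))
                  for i in range(n)]
        return sk.make_toy_frames(atoms)[0]

    def test_unit_mass_com_separation(self):
        frame = self.two_clouds()
        assert st.lobe_separation(frame, mass_weighted=False) \
            == pytest.approx(57.0, abs=1e-9)

    def test_mass_weighted_equals_unit_for_single_element(self):
        frame = self.two_clouds()
        assert st.lobe_separation(frame, mass_weighted=True) \
            == pytest.approx(57.0, abs=1e-9)

    def test_mirror_symmetric_dimer(self):
        # COM separation equals twice the distance of one lobe COM from the
        # mirror plane
        frame = self.two_clouds(sep=40.0, seed=1)
        assert st.lobe_separation(frame, mass_weighted=False) \
            == pytest.approx(2 * 20.0, abs=1e-9)

    def test_empty_selection_rejected(self):
        frame = self.two_clouds()
        with pytest.raises(ValueError):
            st.lobe_separation(frame, chains=("A", "C"), mass_weighted=False)


class TestHbond:
    def test_linear_short_contact_present(self):
        assert st.hbond_present([0, 0, 0], [1, 0, 0], [3.0, 0, 0])

    def test_distance_cutoff(self):
        assert not st.hbond_present([0, 0, 0], [1, 0, 0], [3.6, 0, 0])

    def test_angle_cutoff(self):
        a = [1 + 2.0 * np.cos(np.radians(60)), 2.0 * np.sin(np.radians(60)), 0]
        assert not st.hbond_present([0, 0, 0], [1, 0, 0], a)

    def test_residue_contact_is_or_over_triplets(self):
        good = ([0, 0, 0], [1, 0, 0], [3.0, 0, 0])
        bad = ([0, 0, 0], [1, 0, 0], [3.6, 0, 0])
        assert st.any_hbond([bad, good])
        assert not st.any_hbond([bad, bad])


class TestWindowRmsf:
    def chain(self, n=40, start=160):
        return [("A", start + i, "GLY", "CA", "C", (3.8 * i, 0.0, 0.0))
                for i in range(n)]

    def test_static_frames_zero_rmsf(self):
        frames = sk.make_toy_frames(self.chain(), n_frames=6)
        table = st.window_rmsf(frames, chain="A",
                               align_residues=((160, 170), (185, 195)),
                               rmsf_residues=(170, 185))
        assert np.allclose(table["rmsf_A"], 0.0, atol=1e-12)

    def test_oscillating_atom_rmsf_is_amplitude(self):
        disp = np.zeros((10, 40, 3))
        disp[::2, 20, 0] = 1.0
        disp[1::2, 20, 0] = -1.0
        frames = sk.make_toy_frames(self.chain(), n_frames=10,
                                    displacements=disp)
        table = st.window_rmsf(frames, chain="A",
                               align_residues=((160, 170), (185, 195)),
                               rmsf_residues=(170, 185))
        osc = table.loc[table.resnum == 180, "rmsf_A"].item()
        assert osc == pytest.approx(1.0, abs=1e-9)
        assert table.loc[table.resnum != 180, "rmsf_A"].max() < 1e-9

    def test_global_translation_removed_by_alignment(self):
        disp = np.zeros((6, 40, 3))
        disp[:, :, 1] = np.arange(6)[:, None] * 5.0   # drifting frames
        frames = sk.make_toy_frames(self.chain(), n_frames=6,
                                    displacements=disp)
        table = st.window_rmsf(frames, chain="A",
                               align_residues=((160, 170), (185, 195)),
                               rmsf_residues=(170, 185))
        assert np.allclose(table["rmsf_A"], 0.0, atol=1e-9)


class TestInterhelixAngle:
    def test_parallel_helices(self):
        atoms = ideal_helix("A") + ideal_helix("B", offset=(20, 0, 0))
        frame = sk.make_toy_frames(atoms)[0]
        assert st.interhelix_angle(frame) == pytest.approx(0.0, abs=1e-6)

    def test_thirty_degree_rotation(self):
        rot = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        atoms = ideal_helix("A") + ideal_helix("B", transform=rot,
                                               offset=(20, 0, 0))
        frame = sk.make_toy_frames(atoms)[0]
        assert st.interhelix_angle(frame) == pytest.approx(30.0, abs=0.5)

    def test_antiparallel_directed_vs_undirected(self):
        # inversion maps the principal axis to exactly its negative
        inversion = -np.eye(3)
        atoms = ideal_helix("A") + ideal_helix("B", transform=inversion,
                                               offset=(20, 0, 0))
        frame = sk.make_toy_frames(atoms)[0]
        assert st.interhelix_angle(frame) == pytest.approx(180.0, abs=1e-6)
        assert st.interhelix_angle(frame, directed=False) \
            == pytest.approx(0.0, abs=1e-6)

    def test_rigid_invariance(self):
        rot30 = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        atoms = ideal_helix("A") + ideal_helix("B", transform=rot30,
                                               offset=(20, 0, 0))
        frame = sk.make_toy_frames(atoms)[0]
        grot, gtrans = random_rigid(3)
        assert st.interhelix_angle(frame.transformed(grot, gtrans)) \
            == pytest.approx(st.interhelix_angle(frame), abs=1e-6)


class TestFileIo:
    def test_multimodel_pdb_roundtrip(self, tmp_path):
        atoms = [("A", 248, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
                 ("B", 248, "ALA", "CA", "C", (38.2, 0.0, 0.0))]
        frames = sk.make_toy_frames(atoms, n_frames=3, jitter_sd=0.2, seed=1)
        path = tmp_path / "toy.pdb"
        st.write_pdb(path, frames)
        back = st.read_structure_frames(path)
        assert len(back) == 3
        spec = st.ResiduePairSpec("x", "A", 248, "B", 248)
        for orig, re_read in zip(frames, back):
            # PDB coordinates carry three decimals
            assert st.pair_distance(re_read, spec) \
                == pytest.approx(st.pair_distance(orig, spec), abs=5e-3)

    def test_metrics_table_aligns_models(self, tmp_path):
        atoms = [("A", 248, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
                 ("B", 248, "ALA", "CA", "C", (30.0, 0.0, 0.0))]
        frames = sk.make_toy_frames(atoms, n_frames=4)
        spec = st.ResiduePairSpec("LBD-LBD", "A", 248, "B", 248)
        table = st.metrics_table(frames, [spec])
        assert list(table["model"]) == [0, 1, 2, 3]
        assert np.allclose(table["value"], 30.0)
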