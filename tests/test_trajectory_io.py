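"""Trajectory I/O: PDB/XYZ round trips, error contracts, atom selection."""

import numpy as np
import pytest

from aquaperm.trajectory_io import (
    ParseError,
    SelectionError,
    StructureError,
    Trajectory,
    read_pdb,
    read_xyz_multiframe,
    select_atoms,
    select_single_atom,
    write_pdb,
    write_xyz,
)

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  O   HOH A   2       8.000   1.500   2.250  1.00  0.00           O
END
"""

PDB_2MODELS = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A   3       0.000   2.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   1.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       1.000   0.000   1.000  1.00  0.00           C
ATOM      3  CA  SER A   3       0.000   2.000   1.000  1.00  0.00           C
ENDMDL
END
"""


class TestReadPdb:
    def test_single_model(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(PDB_3ATOMS)
        traj = read_pdb(str(p))
        assert traj.n_frames == 1
        assert traj.n_atoms == 3
        assert traj.topology[1].name == "CA"
        assert traj.topology[1].element == "C"
        assert traj.topology[2].residue_name == "HOH"
        np.testing.assert_allclose(
            traj.frames[0].coords[2], [8.0, 1.5, 2.25], atol=1e-6
        )

    def test_two_models_share_topology(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(PDB_2MODELS)
        traj = read_pdb(str(p))
        assert traj.n_frames == 2
        names = [a.name for a in traj.topology]
        assert names == ["CA", "CA", "CA"]
        assert traj.frames[1].coords[0, 2] == pytest.approx(1.0)

    def test_vdw_radii_assigned(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(PDB_3ATOMS)
        traj = read_pdb(str(p))
        assert traj.topology[0].vdw_radius == pytest.approx(1.55)  # N, Bondi
        assert traj.topology[2].vdw_radius == pytest.approx(1.52)  # O, Bondi

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  CA  ALA A   1      bad coords here\n")
        with pytest.raises(ParseError, match=":1"):
            read_pdb(str(p))

    def test_unknown_element_warns_and_defaults(self, tmp_path):
        p = tmp_path / "x.pdb"
        p.write_text(
            "ATOM      1  XX  UNK A   1       0.000   0.000   0.000"
            "  1.00  0.00          XX\n"
        )
        with pytest.warns(UserWarning, match="default vdW radius"):
            traj = read_pdb(str(p), default_radius=1.7)
        assert traj.topology[0].vdw_radius == pytest.approx(1.7)


class TestRoundTrips:
    def test_pdb_roundtrip_within_format_precision(self, small_sim, tmp_path):
        _, traj, _, _, _ = small_sim
        sub = Trajectory(traj.topology, traj.frames[:3], traj.frame_interval)
        path = tmp_path / "rt.pdb"
        write_pdb(sub, str(path))
        back = read_pdb(str(path), frame_interval=traj.frame_interval)
        assert back.n_frames == 3
        assert [a.name for a in back.topology] == [a.name for a in sub.topology]
        assert np.abs(
            back.coordinate_array() - sub.coordinate_array()
        ).max() < 1e-3

    def test_xyz_roundtrip_exact_to_written_precision(self, small_sim, tmp_path):
        _, traj, _, _, _ = small_sim
        sub = Trajectory(traj.topology, traj.frames[:5], traj.frame_interval)
        path = tmp_path / "rt.xyz"
        write_xyz(sub, str(path))
        back = read_xyz_multiframe(
            str(path), topology=sub.topology, frame_interval=sub.frame_interval
        )
        assert back.n_frames == 5
        assert np.abs(back.coordinate_array() - sub.coordinate_array()).max() < 1e-5


class TestReadXyz:
    def test_multiframe(self, tmp_path):
        text = ""
        for f in range(5):
            text += f"2\nframe {f}\nO 0 0 {f} \nH 1 0 {f}\n"
        p = tmp_path / "t.xyz"
        p.write_text(text)
        traj = read_xyz_multiframe(str(p), frame_interval=2.0)
        assert traj.n_frames == 5
        assert traj.times[-1] == pytest.approx(8.0)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.xyz"
        p.write_text("")
        with pytest.raises(ParseError):
            read_xyz_multiframe(str(p))

    def test_atom_count_mismatch(self, small_sim, tmp_path):
        _, traj, _, _, _ = small_sim
        p = tmp_path / "t.xyz"
        p.write_text("1\nframe\nO 0 0 0\n")
        with pytest.raises(StructureError):
            read_xyz_multiframe(str(p), topology=traj.topology)


class TestSelection:
    def test_name_resnum_chain(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(PDB_3ATOMS)
        traj = read_pdb(str(p))
        assert list(select_atoms(traj, "name=CA and resnum=1 and chain=A")) == [1]
        assert select_single_atom(traj, "name=O and resnum=2") == 2

    def test_water_oxygens(self, small_sim):
        _, traj, _, _, _ = small_sim
        ow = select_atoms(traj, "name=OW")
        n_waters = sum(1 for a in traj.topology if a.name == "OW")
        assert len(ow) == n_waters

    def test_complement_partitions_the_topology(self, small_sim):
        _, traj, _, _, _ = small_sim
        sel = set(select_atoms(traj, "element=O"))
        comp = {a.index for a in traj.topology} - sel
        assert len(sel) + len(comp) == traj.n_atoms

    def test_selection_is_topology_only(self, small_sim):
        _, traj, _, _, _ = small_sim
        a = select_atoms(traj, "name=OW and chain=A")
        shifted = Trajectory(
            traj.topology,
            [type(traj.frames[0])(time=0.0, coords=traj.frames[0].coords + 50.0)],
            traj.frame_interval,
        )
        assert list(select_atoms(shifted, "name=OW and chain=A")) == list(a)

    @pytest.mark.parametrize("bad", ["name", "foo=1", "resnum=abc", "name=CA and "])
    def test_malformed_queries(self, small_sim, bad):
        _, traj, _, _, _ = small_sim
        with pytest.raises(SelectionError):
            select_atoms(traj, bad)

    def test_single_atom_requires_uniqueness(self, small_sim):
        _, traj, _, _, _ = small_sim
        with pytest.raises(SelectionError, match="exactly one"):
            select_single_atom(traj, "name=OW")


def test_frame_times_must_increase(small_sim):
    _, traj, _, _, _ = small_sim
    f0, f1 = traj.frames[0], traj.frames[1]
    bad0 = type(f0)(time=5.0, coords=f0.coords)
    bad1 = type(f1)(time=1.0, coords=f1.coords)
    with pytest.raises(ValueError, match="strictly increasing"):
        Trajectory(traj.topology, [bad0, bad1], traj.frame_interval)
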