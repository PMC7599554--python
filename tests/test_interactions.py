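"""Interaction detectors on synthetic planted-geometry complexes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from agelascreen import fixtures, interactions as ia


def transform_complex(lig, rec, rot, t):
    lig2 = ia.LigandStructure(lig.name, list(lig.atom_names),
                              list(lig.elements), lig.coords @ rot.T + t)
    residues = [ia.Residue(r.chain, r.number, r.name, list(r.atom_names),
                           list(r.elements), r.coords @ rot.T + t)
                for r in rec.residues]
    return lig2, ia.ReceptorModel(residues)


class TestLoadComplex:
    def test_split(self, standard_pose):
        path, spec = standard_pose
        lig, rec = ia.load_complex(path, "LIG")
        assert lig.name == "LIG"
        assert len(rec.residues) == len(spec)
        assert all(r.name != "LIG" for r in rec.residues)

    def test_selector_matches_nothing(self, standard_pose):
        with pytest.raises(ValueError, match="matched nothing"):
            ia.load_complex(standard_pose[0], "XYZ")

    def test_two_ligand_copies_error(self, tmp_path):
        path = tmp_path / "two.pdb"
        fixtures.make_fixture_complex([], path, second_ligand=True)
        with pytest.raises(ValueError, match="matched several"):
            ia.load_complex(path, "LIG")


class TestHbonds:
    def test_planted_geometry_detected(self, tmp_path):
        path = tmp_path / "hb.pdb"
        fixtures.make_fixture_complex(
            [{"type": "hbond", "role": "ligand_donor", "distance": 2.9,
              "angle": 160.0, "residue": ("A", 2873, "U")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        records = ia.detect_hbonds(lig, rec)
        assert len(records) == 1
        r = records[0]
        assert (r.residue, r.ligand_atom) == ("U2873", "N1")
        assert r.distance == pytest.approx(2.9, abs=0.05)
        assert r.angle == pytest.approx(160.0, abs=2.0)

    def test_beyond_distance_cutoff(self, tmp_path):
        path = tmp_path / "far.pdb"
        fixtures.make_fixture_complex(
            [{"type": "hbond", "role": "ligand_donor", "distance": 4.0,
              "angle": 160.0, "residue": ("A", 2873, "U")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        assert ia.detect_hbonds(lig, rec) == []

    def test_below_angle_cutoff(self, tmp_path):
        path = tmp_path / "bent.pdb"
        fixtures.make_fixture_complex(
            [{"type": "hbond", "role": "ligand_donor", "distance": 2.9,
              "angle": 90.0, "residue": ("A", 2873, "U")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        assert [r for r in ia.detect_hbonds(lig, rec)
                if r.residue == "U2873" and r.ligand_atom == "N1"] == []

    def test_monotone_in_distance_cutoff(self, standard_pose):
        lig, rec = ia.load_complex(standard_pose[0], "LIG")
        small = {r.key() for r in ia.detect_hbonds(lig, rec, d_max=3.0)}
        large = {r.key() for r in ia.detect_hbonds(lig, rec, d_max=3.5)}
        assert small <= large


class TestHalogen:
    def test_on_normal_detected(self, tmp_path):
        path = tmp_path / "xpi.pdb"
        fixtures.make_fixture_complex(
            [{"type": "halogen_pi", "distance": 3.4,
              "residue": ("A", 2875, "U")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        recs = [r for r in ia.detect_halogen_pi(lig, rec)
                if r.type == "halogen_pi"]
        assert len(recs) == 1
        assert recs[0].residue == "U2875"
        assert recs[0].distance == pytest.approx(3.4, abs=0.05)

    def test_in_plane_not_detected(self, tmp_path):
        path = tmp_path / "xplane.pdb"
        fixtures.make_fixture_complex(
            [{"type": "halogen_pi", "distance": 3.4, "off_normal": 90.0,
              "residue": ("A", 2875, "U")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        assert [r for r in ia.detect_halogen_pi(lig, rec)
                if r.type == "halogen_pi"] == []

    def test_halogen_free_ligand_gives_no_records(self, tmp_path):
        """A debromo-type ligand (no halogens) can never produce halogen
        records, whatever the receptor."""
        path = tmp_path / "nohal.pdb"
        fixtures.make_fixture_complex(
            [{"type": "halogen_pi", "distance": 3.4,
              "residue": ("A", 2875, "U")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        keep = [i for i, n in enumerate(lig.atom_names) if n != "CL1"]
        stripped = ia.LigandStructure(
            "LIG", [lig.atom_names[i] for i in keep],
            [lig.elements[i] for i in keep], lig.coords[keep])
        assert ia.detect_halogen_pi(stripped, rec) == []


class TestStacking:
    def test_parallel(self, tmp_path):
        path = tmp_path / "par.pdb"
        fixtures.make_fixture_complex(
            [{"type": "pi_stack", "distance": 3.6, "geometry": "parallel",
              "residue": ("A", 2821, "C")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        recs = ia.detect_stacking(lig, rec)
        assert len(recs) == 1
        assert recs[0].detail == "parallel"
        assert recs[0].distance == pytest.approx(3.6, abs=0.05)

    def test_t_shaped(self, tmp_path):
        path = tmp_path / "t.pdb"
        fixtures.make_fixture_complex(
            [{"type": "pi_stack", "distance": 4.8, "geometry": "t",
              "residue": ("A", 2821, "C")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        recs = ia.detect_stacking(lig, rec)
        assert len(recs) == 1
        assert recs[0].detail == "t-shaped"

    def test_distant_rings_ignored(self, tmp_path):
        path = tmp_path / "farring.pdb"
        fixtures.make_fixture_complex(
            [{"type": "pi_stack", "distance": 8.0, "geometry": "parallel",
              "residue": ("A", 2821, "C")}], path)
        lig, rec = ia.load_complex(path, "LIG")
        assert ia.detect_stacking(lig, rec) == []


class TestShellAndBurial:
    def test_planted_nine_residue_shell(self, shell9_pose):
        path, residues = shell9_pose
        lig, rec = ia.load_complex(path, "LIG")
        shell = ia.contact_shell(lig, rec)
        assert len(shell) == 9
        assert shell == [f"{name}{num}" for _, num, name in residues]

    def test_isolated_ligand_empty_shell_and_unburied(self, tmp_path):
        path = tmp_path / "alone.pdb"
        fixtures.make_fixture_complex([], path)
        lig, rec = ia.load_complex(path, "LIG")
        assert ia.contact_shell(lig, rec) == []
        assert ia.buried_fraction(lig, rec) == 0.0

    def test_tiny_cutoff_empty_shell(self, shell9_pose):
        lig, rec = ia.load_complex(shell9_pose[0], "LIG")
        assert ia.contact_shell(lig, rec, d_max=0.1) == []

    def test_caged_ligand_nearly_fully_buried(self, tmp_path):
        path = tmp_path / "cage.pdb"
        fixtures.make_fixture_complex([{"type": "cage"}], path)
        lig, rec = ia.load_complex(path, "LIG")
        assert ia.buried_fraction(lig, rec) >= 0.95

    def test_wall_partially_buries(self, tmp_path):
        path = tmp_path / "wall.pdb"
        fixtures.make_fixture_complex([{"type": "wall", "distance": 3.5}], path)
        lig, rec = ia.load_complex(path, "LIG")
        assert 0.2 <= ia.buried_fraction(lig, rec) <= 0.8

    def test_shell_monotone_in_cutoff(self, shell9_pose):
        lig, rec = ia.load_complex(shell9_pose[0], "LIG")
        assert set(ia.contact_shell(lig, rec, d_max=4.2)) <= set(
            ia.contact_shell(lig, rec, d_max=4.5))


class TestInvariance:
    def test_rigid_transform_leaves_detections_unchanged(self, standard_pose):
        lig, rec = ia.load_complex(standard_pose[0], "LIG")
        before = ia.fingerprint(lig, rec)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        lig2, rec2 = transform_complex(lig, rec, rot, np.array([5.0, -3.0, 2.0]))
        after = ia.fingerprint(lig2, rec2)
        assert {r.key() for r in before.records} == {r.key() for r in after.records}
        b = {r.key(): r for r in before.records}
        a = {r.key(): r for r in after.records}
        for k in b:
            assert a[k].distance == pytest.approx(b[k].distance, abs=1e-3)
        assert before.shell == after.shell
        assert after.buried == pytest.approx(before.buried, abs=0.02)

    def test_planted_set_recovered_exactly(self, standard_pose):
        """At default thresholds the detected records are exactly the
        planted ones — no false positives."""
        lig, rec = ia.load_complex(standard_pose[0], "LIG")
        rep = ia.fingerprint(lig, rec)
        expected = {("hbond", "N1", "U2873"), ("hbond", "O1", "U2869"),
                    ("halogen_pi", "CL1", "U2875"), ("pi_stack", "C2", "C2821")}
        assert {r.key() for r in rep.records} == expected


class TestBuildMap:
    def test_empty_report_row(self, tmp_path):
        path = tmp_path / "alone.pdb"
        fixtures.make_fixture_complex([], path)
        lig, rec = ia.load_complex(path, "LIG")
        rep = ia.fingerprint(lig, rec)
        matrix, payload = ia.build_map([rep])
        assert list(matrix.index) == ["LIG"]
        assert matrix.shape[1] == 0
        assert payload["LIG"]["records"] == []

    def test_shared_residue_counts(self, standard_pose):
        lig, rec = ia.load_complex(standard_pose[0], "LIG")
        rep1 = ia.fingerprint(lig, rec)
        rep2 = ia.FingerprintReport(ligand="OTHER", records=list(rep1.records),
                                    shell=list(rep1.shell), buried=rep1.buried)
        matrix, _ = ia.build_map([rep1, rep2])
        assert (matrix.loc["LIG"] == matrix.loc["OTHER"]).all()
        assert matrix.loc[:, "U2873:hbond"].sum() == 2

    def test_extra_hbond_superset_narrative(self, tmp_path):
        """An analogue gaining one H-bond at the U2873-type residue shows as
        a strict superset of the parent's interaction row."""
        base_spec = [{"type": "hbond", "role": "ligand_acceptor",
                      "distance": 2.9, "angle": 170.0,
                      "residue": ("A", 2869, "U")}]
        extra_spec = base_spec + [
            {"type": "hbond", "role": "ligand_donor", "distance": 2.9,
             "angle": 160.0, "residue": ("A", 2873, "U")}]
        p1, p2 = tmp_path / "aa.pdb", tmp_path / "ceaa.pdb"
        fixtures.make_fixture_complex(base_spec, p1)
        fixtures.make_fixture_complex(extra_spec, p2)
        lig1, rec1 = ia.load_complex(p1, "LIG")
        lig2, rec2 = ia.load_complex(p2, "LIG")
        rep_parent = ia.fingerprint(lig1, rec1)
        rep_analog = ia.fingerprint(lig2, rec2)
        parent_keys = {r.key() for r in rep_parent.records}
        analog_keys = {r.key() for r in rep_analog.records}
        assert parent_keys < analog_keys
        assert analog_keys - parent_keys == {("hbond", "N1", "U2873")}
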