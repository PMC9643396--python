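"""Contact classification, clash detection, dihedrals, rotamers and RMSD."""

import math

import numpy as np
import pytest

from crydiscov.errors import AnalysisError, StructureParseError
from crydiscov.structure_analysis import (
    Atom,
    ContactCutoffs,
    Pose,
    ProteinStructure,
    Residue,
    Trajectory,
    chi1_series,
    com_distance,
    detect_clashes,
    detect_contacts,
    dihedral,
    load_structure,
    rotamer_summary,
    superpose_rmsd,
    write_pdb,
)
from crydiscov.synthetic_data import gen_pocket_and_pose, gen_rotamer_trajectory


def _simple_protein():
    return ProteinStructure([
        Residue("A", 1, "GLY", [
            Atom("N", "N", [0.0, 0.0, 0.0]),
            Atom("CA", "C", [1.46, 0.0, 0.0]),
            Atom("C", "C", [2.0, 1.4, 0.0]),
        ]),
        Residue("A", 2, "GLY", [
            Atom("N", "N", [3.3, 1.5, 0.0]),
            Atom("CA", "C", [4.4, 2.4, 0.0]),
            Atom("C", "C", [5.8, 2.0, 0.0]),
        ]),
    ])


# ---------------------------------------------------------------------- I/O


def test_pdb_round_trip_protein(tmp_path):
    path = tmp_path / "prot.pdb"
    write_pdb(path, _simple_protein())
    loaded = load_structure(path)
    assert isinstance(loaded, ProteinStructure)
    assert len(loaded.residues) == 2
    np.testing.assert_allclose(
        loaded.residues[0].atom("CA").coord, [1.46, 0.0, 0.0], atol=1e-3
    )


def test_pdb_multi_model_becomes_trajectory(tmp_path, vonmises_trajectory):
    traj = vonmises_trajectory.trajectory
    small = Trajectory(atom_table=traj.atom_table, coords=traj.coords[:3], dt=traj.dt)
    path = tmp_path / "traj.pdb"
    write_pdb(path, small)
    loaded = load_structure(path)
    assert isinstance(loaded, Trajectory)
    assert loaded.n_frames == 3
    np.testing.assert_allclose(loaded.coords, small.coords, atol=1e-3)


def test_pdb_hetatm_only_becomes_pose(tmp_path):
    pose = Pose(atoms=[Atom("C1", "C", [0.0, 0.0, 0.0]), Atom("O1", "O", [1.2, 0.0, 0.0])])
    path = tmp_path / "pose.pdb"
    write_pdb(path, pose)
    loaded = load_structure(path)
    assert isinstance(loaded, Pose)
    assert [a.element for a in loaded.atoms] == ["C", "O"]


def test_pdb_nan_coordinate_rejected(tmp_path):
    path = tmp_path / "nan.pdb"
    line = (
        "ATOM      1  CA  GLY A   1     "
        "   nan   0.000   0.000  1.00  0.00           C"
    )
    path.write_text(line + "\n")
    with pytest.raises(StructureParseError, match="line 1"):
        load_structure(path)


def test_pdb_malformed_coordinate_names_line(tmp_path):
    good = (
        "ATOM      1  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C"
    )
    bad = (
        "ATOM      2  CB  GLY A   1       x.yzw   0.000   0.000  1.00  0.00           C"
    )
    path = tmp_path / "bad.pdb"
    path.write_text(good + "\n" + bad + "\n")
    with pytest.raises(StructureParseError, match="line 2"):
        load_structure(path)


# ----------------------------------------------------------------- contacts


def test_single_pi_alkyl_contact_detected():
    pocket = gen_pocket_and_pose(seed=1, contact_spec=[("TRP", "pi-alkyl", 3.8)])
    report = detect_contacts(pocket.protein, pocket.pose)
    pi_alkyl = [c for c in report.contacts if c.kind == "pi-alkyl"]
    assert len(pi_alkyl) == 1
    assert pi_alkyl[0].residue_id.endswith("TRP")
    assert pi_alkyl[0].distance == pytest.approx(3.8, abs=1e-6)


def test_hbond_to_arginine_guanidinium():
    pocket = gen_pocket_and_pose(seed=1, contact_spec=[("ARG", "hbond", 2.9)])
    report = detect_contacts(pocket.protein, pocket.pose)
    assert report.fingerprint() == {("A:293:ARG", "hbond")}
    (c,) = report.contacts
    assert c.distance == pytest.approx(2.9, abs=1e-6)


def test_four_residue_fingerprint_matches_ground_truth(four_contact_pocket):
    report = detect_contacts(four_contact_pocket.protein, four_contact_pocket.pose)
    assert report.fingerprint() == four_contact_pocket.fingerprint()


def test_empty_contact_spec_gives_isolated_pose():
    pocket = gen_pocket_and_pose(seed=4, contact_spec=[])
    report = detect_contacts(pocket.protein, pocket.pose)
    assert report.contacts == []
    lig = pocket.pose.coords()
    for res in pocket.protein.residues:
        for atom in res.atoms:
            assert np.min(np.linalg.norm(lig - atom.coord, axis=1)) >= 10.0


def test_contact_types_mutually_exclusive_per_pair(four_contact_pocket):
    report = detect_contacts(four_contact_pocket.protein, four_contact_pocket.pose)
    seen = set()
    for c in report.contacts:
        key = (c.residue_id, c.atoms)
        assert key not in seen
        seen.add(key)
    cutoffs = ContactCutoffs()
    limit = {"hbond": cutoffs.hbond, "pi-pi": cutoffs.pi_pi, "pi-alkyl": cutoffs.pi_alkyl}
    for c in report.contacts:
        if c.kind in limit:
            assert c.distance <= limit[c.kind]


def test_contacts_invariant_under_rigid_motion(four_contact_pocket, rng):
    """Applying one rigid-body transform to protein and pose together leaves
    the contact fingerprint unchanged."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
    shift = rng.uniform(-30, 30, size=3)

    def moved_protein(p):
        return ProteinStructure([
            Residue(r.chain, r.number, r.name,
                    [Atom(a.name, a.element, rot @ a.coord + shift, a.aromatic)
                     for a in r.atoms])
            for r in p.residues
        ])

    def moved_pose(p):
        return Pose(
            atoms=[Atom(a.name, a.element, rot @ a.coord + shift, a.aromatic)
                   for a in p.atoms],
            rings=p.rings,
        )

    before = detect_contacts(four_contact_pocket.protein, four_contact_pocket.pose)
    after = detect_contacts(
        moved_protein(four_contact_pocket.protein), moved_pose(four_contact_pocket.pose)
    )
    assert before.fingerprint() == after.fingerprint()


def test_empty_pose_rejected():
    with pytest.raises(AnalysisError):
        Pose(atoms=[])


# ------------------------------------------------------------------ clashes


def test_two_carbons_clash_below_scaled_radii():
    a = Pose(atoms=[Atom("C1", "C", [0.0, 0.0, 0.0])])
    b = Pose(atoms=[Atom("C2", "C", [2.0, 0.0, 0.0])])
    clashes = detect_clashes(a, b)  # 2.0 < 0.7 * 3.4 = 2.38
    assert len(clashes) == 1
    assert clashes[0].overlap == pytest.approx(0.38, abs=1e-9)
    assert detect_clashes(
        a, Pose(atoms=[Atom("C2", "C", [2.5, 0.0, 0.0])])
    ) == []


def test_pose_translated_into_tryptophan_clashes():
    pocket = gen_pocket_and_pose(seed=5, contact_spec=[("TRP", "pi-alkyl", 3.8)])
    trp = next(r for r in pocket.protein.residues if r.name == "TRP")
    target = trp.atom("CZ2").coord
    shifted = Pose(
        atoms=[Atom(a.name, a.element, a.coord - pocket.pose.atoms[0].coord + target)
               for a in pocket.pose.atoms]
    )
    clashes = detect_clashes(pocket.protein, shifted)
    assert clashes
    assert any("TRP" in c.atom_a for c in clashes)
    overlaps = [c.overlap for c in clashes]
    assert overlaps == sorted(overlaps, reverse=True)


# ----------------------------------------------------------- center of mass


def test_com_identical_poses_zero():
    pose = Pose(atoms=[Atom("C1", "C", [1.0, 2.0, 3.0])])
    assert com_distance(pose, pose) == 0.0


def test_com_equal_mass_two_atom_offset():
    a = Pose(atoms=[Atom("C1", "C", [0, 0, 0]), Atom("C2", "C", [2, 0, 0])])
    b = Pose(atoms=[Atom("C1", "C", [1, 0, 0]), Atom("C2", "C", [3, 0, 0])])
    assert com_distance(a, b) == pytest.approx(1.0)


def test_com_excluding_tagged_appendage():
    core_a = [Atom("C1", "C", [0, 0, 0]), Atom("C2", "C", [2, 0, 0])]
    core_b = [Atom("C1", "C", [1, 0, 0]), Atom("C2", "C", [3, 0, 0])]
    linker = [Atom("B1", "S", [50.0, 50.0, 50.0], tag="biotin")]
    a = Pose(atoms=core_a + linker)
    b = Pose(atoms=core_b)
    assert com_distance(a, b, exclude_tags={"biotin"}) == pytest.approx(1.0)
    assert com_distance(a, b) != pytest.approx(1.0)


def test_com_all_excluded_raises():
    a = Pose(atoms=[Atom("B1", "C", [0, 0, 0], tag="biotin")])
    with pytest.raises(AnalysisError):
        com_distance(a, a, exclude_tags={"biotin"})


# ---------------------------------------------------------------- dihedrals


@pytest.mark.parametrize(
    "g, expected",
    [
        ([1.0, 1.0, 0.0], 0.0),  # coplanar syn
        ([1.0, -1.0, 0.0], 180.0),  # coplanar anti
        ([1.0, 0.0, 1.0], -90.0),  # +z quadrant, IUPAC negative
        ([1.0, 0.0, -1.0], 90.0),
    ],
)
def test_dihedral_hand_cases(g, expected):
    value = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], g)
    assert value == pytest.approx(expected, abs=1e-9)


def test_chi1_recovers_generator_ground_truth(vonmises_trajectory):
    series = chi1_series(vonmises_trajectory.trajectory, 1)
    truth = vonmises_trajectory.true_chi1["A:1:TRP"]
    delta = np.abs(((series.angles - truth) + 180.0) % 360.0 - 180.0)
    assert np.max(delta) < 1e-6


def test_chi1_invariant_under_rigid_motion():
    base = gen_rotamer_trajectory(
        [("SER", [-65.0, 175.0], [15.0, 15.0], [0.4, 0.6])], 200, seed=8
    )
    moved = gen_rotamer_trajectory(
        [("SER", [-65.0, 175.0], [15.0, 15.0], [0.4, 0.6])], 200, seed=8,
        rigid_motion=True,
    )
    s0 = chi1_series(base.trajectory, 1)
    s1 = chi1_series(moved.trajectory, 1)
    np.testing.assert_allclose(s0.angles, s1.angles, atol=1e-9)


def test_chi1_missing_gamma_atom_names_residue():
    traj = Trajectory(
        atom_table=[("A", 1, "GLY", "N", "N"), ("A", 1, "GLY", "CA", "C")],
        coords=np.zeros((1, 2, 3)) + np.arange(6).reshape(1, 2, 3),
    )
    with pytest.raises(AnalysisError, match="1"):
        chi1_series(traj, 1)


def test_delta_concentration_gives_exact_angles():
    st = gen_rotamer_trajectory([("TRP", [180.0], [math.inf], [1.0])], 10, seed=1)
    series = chi1_series(st.trajectory, 1)
    np.testing.assert_allclose(series.angles, 180.0, atol=1e-9)


# ----------------------------------------------------------------- rotamers


def test_rotamer_trans_occupancy():
    from crydiscov.structure_analysis import DihedralSeries

    s = DihedralSeries("A:1:TRP", np.full(50, 175.0))
    summary = rotamer_summary(s)
    assert summary.occupancies["trans"] == 1.0
    assert summary.dominant == "trans"
    assert sum(summary.occupancies.values()) == 1.0


def test_rotamer_gauche_minus_dominates_vonmises(vonmises_trajectory):
    series = chi1_series(vonmises_trajectory.trajectory, 1)
    summary = rotamer_summary(series)
    assert summary.dominant == "gauche-"
    assert summary.occupancies["gauche-"] > 0.95
    assert abs(summary.circular_mean - (-65.0)) < 2.0
    assert summary.resultant_length > 0.9


def test_rotamer_uniform_occupancies_near_thirds(rng):
    from crydiscov.structure_analysis import DihedralSeries

    angles = rng.uniform(-180.0, 180.0, size=10_000)
    angles[angles <= -180.0] = 180.0
    summary = rotamer_summary(DihedralSeries("A:1:SER", angles))
    for occ in summary.occupancies.values():
        assert abs(occ - 1.0 / 3.0) < 0.05
    assert sum(summary.occupancies.values()) == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------------- RMSD


def _rotate_structure(p, rot, shift=(0.0, 0.0, 0.0)):
    return ProteinStructure([
        Residue(r.chain, r.number, r.name,
                [Atom(a.name, a.element, rot @ a.coord + np.asarray(shift), a.aromatic)
                 for a in r.atoms])
        for r in p.residues
    ])


def test_rmsd_identical_and_translated_frames_zero():
    prot = _simple_protein()
    for mode in ("full", "center-only"):
        value, _ = superpose_rmsd(prot, prot, mode=mode)
        assert value == pytest.approx(0.0, abs=1e-12)
        shifted = _rotate_structure(prot, np.eye(3), (5.0, -3.0, 2.0))
        value, _ = superpose_rmsd(prot, shifted, mode=mode)
        assert value == pytest.approx(0.0, abs=1e-9)


def test_rmsd_pure_rotation_center_only_positive_full_zero():
    prot = _simple_protein()
    theta = math.radians(30.0)
    rot = np.array([
        [math.cos(theta), -math.sin(theta), 0.0],
        [math.sin(theta), math.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    rotated = _rotate_structure(prot, rot)
    center_only, _ = superpose_rmsd(prot, rotated, mode="center-only")
    full, transform = superpose_rmsd(prot, rotated, mode="full")
    assert center_only > 0.1
    assert full == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(transform.rotation) == pytest.approx(1.0)


def test_full_rmsd_never_exceeds_center_only(rng):
    """Kabsch rotation can only reduce the centered residual (100 random pairs)."""
    prot = _simple_protein()
    for _ in range(100):
        perturbed = ProteinStructure([
            Residue(r.chain, r.number, r.name,
                    [Atom(a.name, a.element, a.coord + rng.normal(scale=0.8, size=3))
                     for a in r.atoms])
            for r in prot.residues
        ])
        c, _ = superpose_rmsd(prot, perturbed, mode="center-only")
        f, _ = superpose_rmsd(prot, perturbed, mode="full")
        assert f <= c + 1e-9


def test_rmsd_mismatched_selection_raises():
    prot = _simple_protein()
    other = ProteinStructure([prot.residues[0]])
    with pytest.raises(AnalysisError):
        superpose_rmsd(prot, other)


def test_per_residue_rmsd_keys():
    prot = _simple_protein()
    _, _, per_res = superpose_rmsd(prot, prot, per_residue=True)
    assert set(per_res) == {("A", 1), ("A", 2)}
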