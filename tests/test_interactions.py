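import numpy as np
import pytest
from hypothesis import given, strategies as st

from dockprof.interactions import (
    InteractionParams,
    detect_interactions,
    interaction_report,
    perceive_frame,
    perceive_ligand,
)
from dockprof.io_structures import Atom, ReceptorFrame, ResidueId

from conftest import make_pose


def build_frame(residues, frame_id="frame_000", waters=None):
    """Frame from [(resname, resnum, [(atom, element, xyz), ...]), ...]."""
    frame = ReceptorFrame(frame_id=frame_id)
    for resname, resnum, atoms in residues:
        frame.residues.append(ResidueId("A", resnum, "", resname))
        ridx = len(frame.residues) - 1
        for name, el, xyz in atoms:
            frame.atoms.append(Atom(name, el, np.asarray(xyz, float), ridx))
    frame.waters = np.asarray(waters, float) if waters is not None else np.zeros((0, 3))
    return frame


# ---------------------------------------------------------------------------
# Chemistry perception
# ---------------------------------------------------------------------------

def test_arg_side_chain_is_cationic_donor():
    frame = build_frame([
        ("ARG", 1, [("NE", "N", (0, 0, 0)), ("NH1", "N", (1, 1, 0)),
                    ("NH2", "N", (1, -1, 0)), ("CZ", "C", (0.7, 0, 0)),
                    ("CB", "C", (-3, 0, 0)), ("CG", "C", (-2, 0, 0))]),
    ])
    chem = perceive_frame(frame)
    assert len(chem.cations) == 1
    donors = {frame.atoms[a].name for _, a in chem.donors}
    assert {"NE", "NH1", "NH2"} <= donors
    expected_centroid = np.mean([(0, 0, 0), (1, 1, 0), (1, -1, 0), (0.7, 0, 0)], axis=0)
    assert np.allclose(chem.cations[0][1], expected_centroid, atol=1e-12)


def test_unknown_residue_skipped_with_warning():
    frame = build_frame([
        ("XYZ", 1, [("C1", "C", (0, 0, 0))]),
        ("SER", 2, [("OG", "O", (5, 0, 0))]),
    ])
    with pytest.warns(UserWarning, match="XYZ"):
        chem = perceive_frame(frame)
    assert chem.skipped_residues == ["A:XYZ1"]
    assert len(chem.donors) == 1  # SER OG survives


def test_metal_ion_registered():
    frame = build_frame([("ZN", 1, [("ZN", "ZN", (0, 0, 0))])])
    chem = perceive_frame(frame)
    assert len(chem.metals) == 1
    assert not chem.skipped_residues


def test_ligand_sulfate_anion_centroid(toy_ligand):
    pose = make_pose(toy_ligand.coords)
    chem = perceive_ligand(pose)
    assert len(chem.anions) == 1
    assert set(chem.anions[0]) == {9, 10, 11}  # the three terminal sulfate oxygens


def test_ligand_ring_and_halogen_and_hydrophobics(toy_ligand):
    pose = make_pose(toy_ligand.coords)
    chem = perceive_ligand(pose)
    assert chem.rings == [(14, 15, 16, 17, 18, 19)]
    assert chem.halogens == [(13, 17)]
    assert 12 in chem.hydrophobic  # linker C bonded only to carbons
    assert 17 not in chem.hydrophobic  # ring C carrying Cl
    # ring centroid equals the mean of the ring coordinates
    ring = np.array([pose.coords[i] for i in chem.rings[0]])
    assert np.allclose(ring.mean(axis=0), pose.coords[[14, 15, 16, 17, 18, 19]].mean(axis=0),
                       atol=1e-12)


def test_ligand_hydroxyls_are_donors_and_acceptors(toy_ligand):
    chem = perceive_ligand(make_pose(toy_ligand.coords))
    for o in (1, 3, 5):
        assert o in chem.donors
        assert o in chem.acceptors
    assert 9 in chem.acceptors  # charged sulfate O accepts
    assert 9 not in chem.donors


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def test_sulfate_near_lysine_gives_hbond_and_ionic(toy_ligand):
    """A ligand sulfate oxygen 3.4 Å from Lys NZ: both an H-bond and a salt
    bridge are recorded for that residue."""
    pose = make_pose(toy_ligand.coords)
    chem = perceive_ligand(pose)
    centroid = pose.coords[list(chem.anions[0])].mean(axis=0)
    o9 = pose.coords[9]
    axis = (o9 - centroid) / np.linalg.norm(o9 - centroid)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    nz = o9 + 3.4 * perp  # 3.4 A from the sulfate O, ~3.6 A from the anion centroid
    assert np.linalg.norm(nz - centroid) < 4.0
    frame = build_frame([
        ("LYS", 79, [("NZ", "N", nz), ("CE", "C", nz + perp * 1.5)]),
    ])
    records = detect_interactions(pose, frame, toy_ligand.moiety_scheme())
    types = {r.itype for r in records if r.residue.resnum == 79}
    assert "hbond" in types
    assert "ionic" in types
    assert all(r.moiety == "sulfate" for r in records
               if r.itype in ("hbond", "ionic"))


def test_far_protein_gives_no_records(toy_ligand):
    pose = make_pose(toy_ligand.coords)
    frame = build_frame([
        ("SER", 1, [("OG", "O", (50, 50, 50)), ("CB", "C", (51, 50, 50))]),
    ])
    assert detect_interactions(pose, frame, toy_ligand.moiety_scheme()) == []


def test_planted_detected_decoys_rejected_on_centre_poses(standard_data):
    """The generator's ground truth: every planted contact is found on its
    target centre pose, no decoy contact anywhere."""
    from dockprof.synthetic import TOY_LIGANDS, _build_centers, _make_pose

    data = standard_data
    lig = TOY_LIGANDS[data.truth["ligand"]]()
    centers = _build_centers(lig, data.spec)
    frame = data.frames[0]
    planted = {(tuple(e["residue"]), e["moiety"], e["itype"]): e["targets"]
               for e in data.truth["planted"]}
    decoys = {(tuple(e["residue"]), e["moiety"], e["itype"]): e["targets"]
              for e in data.truth["decoys"]}
    for j, center in enumerate(centers):
        pose = _make_pose(lig, center, f"c{j}", frame.frame_id, 1, 0.0)
        found = {((r.residue.chain, r.residue.resnum, r.residue.icode, r.residue.resname),
                  r.moiety, r.itype)
                 for r in detect_interactions(pose, frame, data.scheme)}
        for key, targets in planted.items():
            if j in targets:
                assert key in found, f"planted {key} missing in cluster {j}"
        for key, targets in decoys.items():
            if j in targets:
                assert key not in found, f"decoy {key} detected in its target cluster {j}"


def test_deduplication_one_record_per_triple(standard_data):
    from dockprof.synthetic import TOY_LIGANDS, _build_centers, _make_pose

    lig = TOY_LIGANDS[standard_data.truth["ligand"]]()
    centers = _build_centers(lig, standard_data.spec)
    pose = _make_pose(lig, centers[0], "c0", "frame_000", 1, 0.0)
    records = detect_interactions(pose, standard_data.frames[0], standard_data.scheme)
    triples = [r.triple() for r in records]
    assert len(triples) == len(set(triples))


def test_records_moiety_matches_scheme(standard_data):
    from dockprof.synthetic import TOY_LIGANDS, _build_centers, _make_pose

    lig = TOY_LIGANDS[standard_data.truth["ligand"]]()
    centers = _build_centers(lig, standard_data.spec)
    pose = _make_pose(lig, centers[0], "c0", "frame_000", 1, 0.0)
    scheme = standard_data.scheme
    ring = set(lig.probes["ring"]["atoms"])
    for r in detect_interactions(pose, standard_data.frames[0], scheme):
        if r.itype in ("pi_pi", "pi_cation") and r.ligand_atom in ring:
            continue  # ring records carry the majority moiety
        assert r.moiety == scheme.assignment[r.ligand_atom]


@given(st.integers(0, 30))
def test_rigid_invariance_of_record_set(standard_data, seed):
    """Rotating pose and frame together leaves the typed contact set unchanged."""
    import copy

    from scipy.spatial.transform import Rotation

    from dockprof.synthetic import TOY_LIGANDS, _build_centers, _make_pose

    lig = TOY_LIGANDS[standard_data.truth["ligand"]]()
    centers = _build_centers(lig, standard_data.spec)
    pose = _make_pose(lig, centers[0], "c0", "frame_000", 1, 0.0)
    frame = standard_data.frames[0]
    base = {(r.triple(), round(r.distance, 6))
            for r in detect_interactions(pose, frame, standard_data.scheme)}

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(size=3) * 10
    pose2 = _make_pose(lig, pose.coords @ R.T + t, "c0", "frame_000", 1, 0.0)
    frame2 = copy.deepcopy(frame)
    for atom in frame2.atoms:
        atom.coords = R @ atom.coords + t
    if len(frame2.waters):
        frame2.waters = frame2.waters @ R.T + t
    moved = {(r.triple(), round(r.distance, 6))
             for r in detect_interactions(pose2, frame2, standard_data.scheme)}
    assert {k for k, _ in moved} == {k for k, _ in base}
    base_d = dict(base)
    for k, d in moved:
        assert d == pytest.approx(base_d[k], abs=1e-5)


def test_shrinking_cutoffs_never_adds_records(standard_data):
    from dockprof.synthetic import TOY_LIGANDS, _build_centers, _make_pose

    lig = TOY_LIGANDS[standard_data.truth["ligand"]]()
    centers = _build_centers(lig, standard_data.spec)
    pose = _make_pose(lig, centers[0], "c0", "frame_000", 1, 0.0)
    frame = standard_data.frames[0]
    scheme = standard_data.scheme
    default = InteractionParams()
    shrunk = default.override(
        hbond_dist=3.0, ionic_dist=3.5, pipi_dist=5.0, pication_dist=5.5,
        hydrophobic_dist=3.5, halogen_dist=3.0, water_hbond_dist=3.0,
        aromatic_hbond_dist=3.5, metal_dist=2.3,
    )
    full = {r.triple() for r in detect_interactions(pose, frame, scheme, default)}
    small = {r.triple() for r in detect_interactions(pose, frame, scheme, shrunk)}
    assert small <= full


def test_frame_mismatch_is_hard_error(toy_ligand):
    pose = make_pose(toy_ligand.coords, frame_id="frame_001")
    frame = build_frame([("SER", 1, [("OG", "O", (0, 0, 0))])], frame_id="frame_000")
    with pytest.raises(ValueError, match="frame"):
        detect_interactions(pose, frame, toy_ligand.moiety_scheme())


def test_water_hbond_only_with_waters(toy_ligand):
    pose = make_pose(toy_ligand.coords)
    o5 = pose.coords[5]
    out = (o5 - pose.coords.mean(axis=0))
    out /= np.linalg.norm(out)
    thr_pos = o5 + 5.6 * out
    residues = [("THR", 1, [("OG1", "O", thr_pos), ("CB", "C", thr_pos + out)])]
    dry = build_frame(residues)
    wet = build_frame(residues, waters=[o5 + 2.8 * out])
    scheme = toy_ligand.moiety_scheme()
    assert not any(r.itype == "water_hbond" for r in detect_interactions(pose, dry, scheme))
    wet_records = [r for r in detect_interactions(pose, wet, scheme)
                   if r.itype == "water_hbond"]
    assert len(wet_records) == 1
    assert wet_records[0].residue.resname == "THR"
    assert wet_records[0].moiety == "sugar"


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def test_interaction_report_counts(toy_ligand):
    pose = make_pose(toy_ligand.coords)
    chem = perceive_ligand(pose)
    o9 = pose.coords[9]
    d = (o9 - pose.coords[8]) / np.linalg.norm(o9 - pose.coords[8])
    frame = build_frame([
        ("LYS", 79, [("NZ", "N", o9 + 3.0 * d), ("CE", "C", o9 + 4.5 * d)]),
    ])
    records = detect_interactions(pose, frame, toy_ligand.moiety_scheme())
    by_res = interaction_report(records, by="residue")
    by_type = interaction_report(records, by="type")
    assert by_res["A:LYS79"] == len(records)
    assert by_type.sum() == len(records)
    assert interaction_report([], by="residue").empty
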