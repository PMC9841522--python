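"""Atom typing, feature matching, exclusion vetoes, and rigid-motion invariance."""

import numpy as np
import pytest

from vstriage.deck_io import Pose
from vstriage.pharmacophore3d import (
    AlignmentError,
    ExclusionSphere,
    MatchError,
    PharmacophoreFeature,
    PharmacophoreModel,
    match,
    screen_poses,
    type_ligand_atoms,
)


def simple_model(min_required=1, exclusions=()):
    return PharmacophoreModel(
        [PharmacophoreFeature("acceptor_site", (0.0, 0.0, 0.0)),
         PharmacophoreFeature("donor_site", (8.0, 0.0, 0.0))],
        min_required,
        list(exclusions),
    )


def test_typing_water_like_oxygen_is_both(rec):
    assert type_ligand_atoms(rec("O")) == ["both"]


def test_typing_benzene_all_neither(rec):
    assert type_ligand_atoms(rec("c1ccccc1")) == ["neither"] * 6


def test_typing_amide_nitrogen_not_acceptor(rec):
    typing = type_ligand_atoms(rec("CC(=O)NC"))  # N has H: donor only
    assert typing[3] == "donor"


def test_typing_hit_compound(rec):
    r = rec("CS(=O)(=O)c1ccc(cc1)Nc1ncnc2sccc12")
    typing = type_ligand_atoms(r)
    symbols = [a.GetSymbol() for a in r.mol.GetAtoms()]
    # sulfonyl oxygens are acceptors; the anilino NH is a donor
    o_idx = [i for i, s in enumerate(symbols) if s == "O"]
    n_idx = [i for i, s in enumerate(symbols) if s == "N"]
    assert all(typing[i] == "acceptor" for i in o_idx)
    assert any(typing[i] in ("donor", "both") for i in n_idx)


def test_match_zero_distance_feature():
    pose = Pose("x", ["O"], [[0.0, 0.0, 0.0]])
    res = match(pose, ["acceptor"], simple_model(min_required=1))
    assert res.passed and res.matched_features == {0}


def test_match_insufficient_features_fails():
    pose = Pose("x", ["O"], [[0.0, 0.0, 0.0]])
    res = match(pose, ["acceptor"], simple_model(min_required=2))
    assert not res.passed and res.matched_features == {0}


def test_exclusion_hit_vetoes_even_when_features_match():
    model = simple_model(min_required=1,
                         exclusions=[ExclusionSphere((20.0, 0.0, 0.0), 1.4)])
    pose = Pose("x", ["O", "C"], [[0.0, 0.0, 0.0], [19.0, 0.0, 0.0]])
    res = match(pose, ["acceptor", "neither"], model)
    assert not res.passed
    assert res.exclusion_hits == ((1, 0),)


def test_boundary_distance_counts_as_inside():
    model = simple_model(min_required=1)
    pose = Pose("x", ["O"], [[1.4, 0.0, 0.0]])  # exactly the radius
    assert match(pose, ["acceptor"], model).passed
    pose_out = Pose("x", ["O"], [[np.nextafter(1.4, 2.0), 0.0, 0.0]])
    assert not match(pose_out, ["acceptor"], model).passed


def test_wrong_atom_type_does_not_match():
    pose = Pose("x", ["N"], [[0.0, 0.0, 0.0]])
    assert not match(pose, ["donor"], simple_model(min_required=1)).passed


def test_empty_and_misaligned_poses_raise():
    with pytest.raises(MatchError):
        match(Pose("x", ["H"], [[0, 0, 0]]), [], simple_model())
    with pytest.raises(AlignmentError):
        match(Pose("x", ["O", "N"], [[0, 0, 0], [1, 1, 1]]), ["acceptor"], simple_model())


def test_screen_any_pose_semantics():
    model = simple_model(min_required=1)
    good = Pose("cpd", ["O"], [[0.0, 0.0, 0.0]])
    bad = Pose("cpd", ["O"], [[30.0, 0.0, 0.0]])
    passed, rows, best = screen_poses([bad, good], {"cpd": ["acceptor"]}, model)
    assert passed == ["cpd"]
    assert len(rows) == 2
    assert best["cpd"].matched_features == {0}

    passed, rows, _ = screen_poses([bad], {"cpd": ["acceptor"]}, model)
    assert passed == [] and rows[0]["compound_id"] == "cpd"


def test_best_pose_tiebreak_prefers_smaller_distance():
    model = simple_model(min_required=1)
    near = Pose("cpd", ["O"], [[0.5, 0.0, 0.0]])
    nearer = Pose("cpd", ["O"], [[0.1, 0.0, 0.0]])
    _, _, best = screen_poses([near, nearer], {"cpd": ["acceptor"]}, model)
    assert best["cpd"].matched_distance == pytest.approx(0.1)


def _random_rigid_motion(rng):
    M = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(M)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return Q, t


def test_rigid_motion_invariance(funnel, model):
    rng = np.random.default_rng(5)
    poses = funnel["poses"][:40]
    recs = {r.id: r for r in funnel["records"]}
    typings = {p.compound_id: type_ligand_atoms(recs[p.compound_id]) for p in poses}
    base, _, _ = screen_poses(poses, typings, model)
    for _ in range(5):
        R, t = _random_rigid_motion(rng)
        moved = [Pose(p.compound_id, p.elements, p.coords @ R.T + t, p.engine_scores)
                 for p in poses]
        got, _, _ = screen_poses(moved, typings, model.transformed(R, t))
        assert got == base


def test_monotone_in_min_required_and_radius(funnel, model):
    poses = funnel["poses"][:60]
    recs = {r.id: r for r in funnel["records"]}
    typings = {p.compound_id: type_ligand_atoms(recs[p.compound_id]) for p in poses}
    base, _, _ = screen_poses(poses, typings, model)

    stricter = PharmacophoreModel(model.features, model.min_required + 1, model.exclusions)
    smaller = PharmacophoreModel(
        [PharmacophoreFeature(f.kind, f.center, f.radius / 3) for f in model.features],
        model.min_required, model.exclusions)
    no_excl = PharmacophoreModel(model.features, model.min_required, [])
    assert set(screen_poses(poses, typings, stricter)[0]) <= set(base)
    assert set(screen_poses(poses, typings, smaller)[0]) <= set(base)
    assert set(screen_poses(poses, typings, no_excl)[0]) >= set(base)


def test_model_json_round_trip(tmp_path, model):
    path = tmp_path / "model.json"
    model.to_json(path)
    back = PharmacophoreModel.from_json(path)
    assert back == model
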