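"""The generators are pure functions of spec+seed and their plants are
recovered exactly by the pipeline stages."""

import numpy as np
import pytest

from vstriage.consensus_pool import pool
from vstriage.descriptor_filters import stage1_filter
from vstriage.pharmacophore3d import screen_poses, type_ligand_atoms
from vstriage.synthetic_deck import (
    DeckSpec,
    GenerationError,
    default_pharmacophore_model,
    gen_labels,
    gen_molecules,
    gen_poses,
    gen_ranked_lists,
    make_pose_plan,
    _overlap_plan,
)


def small_spec(**kw):
    defaults = dict(
        n_compounds=150,
        seed=5,
        violation_quotas={"aromatic_rings": 7, "hbd": 3, "alert": 2},
        stage2_quota=10,
        top_n=30,
        n_union=50,
    )
    defaults.update(kw)
    return DeckSpec(**defaults)


def test_same_seed_identical_deck():
    r1, t1 = gen_molecules(small_spec())
    r2, t2 = gen_molecules(small_spec())
    assert [(r.id, r.smiles) for r in r1] == [(r.id, r.smiles) for r in r2]
    assert t1 == t2


def test_different_seed_different_order():
    r1, _ = gen_molecules(small_spec())
    r2, _ = gen_molecules(small_spec(seed=6))
    assert [r.smiles for r in r1] != [r.smiles for r in r2]


def test_zero_quotas_all_pass():
    records, truth = gen_molecules(small_spec(violation_quotas={}))
    verdicts = stage1_filter(records)
    assert all(v.passed for v in verdicts)
    assert all(t["stage1_pass"] for t in truth.values())


def test_planted_quota_recovered_per_rule():
    records, truth = gen_molecules(small_spec())
    verdicts = {v.compound_id: v for v in stage1_filter(records)}
    by_rule: dict[str, int] = {}
    for cid, t in truth.items():
        if t["planted_rule"]:
            assert not verdicts[cid].passed
            by_rule[t["planted_rule"]] = by_rule.get(t["planted_rule"], 0) + 1
        else:
            assert verdicts[cid].passed
    assert by_rule == {"aromatic_rings": 7, "hbd": 3, "alert": 2}


def test_infeasible_quota_raises():
    with pytest.raises(GenerationError):
        gen_molecules(DeckSpec(n_compounds=5, violation_quotas={"hbd": 10}))
    with pytest.raises(GenerationError):
        gen_molecules(small_spec(violation_quotas={"tpsa": 500}))


def test_pose_plants_recovered_end_to_end():
    records, truth = gen_molecules(small_spec(violation_quotas={}))
    model = default_pharmacophore_model()
    ids = [r.id for r in records][:60]
    plan = make_pose_plan(ids, model.min_required, pass_fraction=0.6, seed=2)
    poses = gen_poses(records, model, plan, seed=2)
    typings = {r.id: type_ligand_atoms(r) for r in records if r.id in plan}
    passed, _, _ = screen_poses(poses, typings, model)
    expected = sorted(c for c, (n, v) in plan.items() if n >= model.min_required and not v)
    assert passed == expected


def test_pose_exclusion_plant_fails_despite_matches():
    records, _ = gen_molecules(small_spec(violation_quotas={}))
    model = default_pharmacophore_model()
    cid = records[0].id
    poses = gen_poses(records, model, {cid: (model.min_required, True)}, seed=0)
    typings = {cid: type_ligand_atoms(records[0])}
    passed, rows, _ = screen_poses(poses, typings, model)
    assert passed == [] and rows[0]["n_exclusion_hits"] >= 1


def test_gen_poses_geometry_infeasible():
    from vstriage.pharmacophore3d import PharmacophoreFeature, PharmacophoreModel

    overlapping = PharmacophoreModel(
        [PharmacophoreFeature("acceptor_site", (0, 0, 0)),
         PharmacophoreFeature("acceptor_site", (1.0, 0, 0))], 1)
    records, _ = gen_molecules(small_spec(violation_quotas={}))
    with pytest.raises(GenerationError):
        gen_poses(records, overlapping, {records[0].id: (1, False)})


@pytest.mark.parametrize(
    "top_n, n_union",
    [(30, 30), (30, 90), (30, 50), (1000, 2057)],
)
def test_overlap_plan_arithmetic(top_n, n_union):
    x, y, z = _overlap_plan(top_n, n_union)
    assert x + y + z == n_union
    assert 3 * x + 2 * y + z == 3 * top_n


def test_overlap_infeasible():
    with pytest.raises(GenerationError):
        _overlap_plan(30, 29)
    with pytest.raises(GenerationError):
        _overlap_plan(30, 91)


@pytest.mark.parametrize("n_union, expected", [(30, 30), (90, 90), (50, 50)])
def test_ranked_lists_hit_requested_union(n_union, expected):
    ids = [f"c{i:03d}" for i in range(120)]
    lists = gen_ranked_lists(ids, top_n=30, n_union=n_union, seed=8)
    assert len(pool(lists, 30).members) == expected
    directions = {rl.direction for rl in lists}
    assert directions == {"higher", "lower"}  # mixed directions exercised


def test_labels_deterministic_and_extreme_rates():
    ids = [f"c{i}" for i in range(200)]
    assert gen_labels(ids, 0.0, seed=1) == {c: 0 for c in ids}
    assert gen_labels(ids, 1.0, seed=1) == {c: 1 for c in ids}
    assert gen_labels(ids, 0.3, seed=7) == gen_labels(ids, 0.3, seed=7)


def test_label_rate_matches_binomial_expectation():
    ids = [f"c{i}" for i in range(960)]
    rate = 0.005
    observed = [sum(gen_labels(ids, rate, seed=s).values()) / 960 for s in range(200)]
    mean = float(np.mean(observed))
    se = np.sqrt(rate * (1 - rate) / 960) / np.sqrt(200)
    assert abs(mean - rate) <= 3 * se


def test_stage2_plant_exact_quota():
    from vstriage.descriptor_filters import stage2_filter
    from vstriage.synthetic_deck import assign_stage2_properties

    records, _ = gen_molecules(small_spec(violation_quotas={}))
    pool_ids = [r.id for r in records[:80]]
    violators = assign_stage2_properties(records, pool_ids, quota=12, seed=3)
    verdicts = stage2_filter([r for r in records if r.id in set(pool_ids)])
    removed = {v.compound_id for v in verdicts if not v.passed}
    assert removed == violators and len(removed) == 12
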