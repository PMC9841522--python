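"""Synthetic screening inputs with planted ground truth.

Every input the triage pipeline consumes can be generated here with known
labels, so each stage is testable end-to-end without a commercial library
or docking engines:

* a compound deck assembled from a fragment grammar (heteroaryl cores,
  linkers, sulfone/sulfonamide caps) guaranteeing chemical validity, with
  exact per-rule quotas of stage-1 property/alert violators planted by
  construction;
* docked poses whose polar atoms are placed inside a requested number of
  pharmacophore feature spheres (or inside an exclusion sphere when a
  violation is planted), with all other atoms far from every sphere;
* three engine score lists whose top-N overlap structure is solved exactly
  so the consensus pool has a requested size (mixed score directions to
  exercise direction handling);
* caller-supplied logD/PSA columns with an exact quota of stage-2
  violators among the pool members;
* Bernoulli activity labels at a set hit rate.

Every generator is a pure function of its spec and seed: a single integer
seed feeds a named-stream splitter so sub-generators are independently
reproducible.

The defaults mirror the funnel of the screen this package models at desk
scale: a 3000-compound deck (standing in for a 31000-member commercial
kinase-focused library), three top-1000 lists pooling to 2057 unique
compounds, 314 stage-2 violators leaving 1743, k = 960 clusters, a
purchase target of 960 with a top-50 augmentation, and a 0.5% hit rate.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np

from .consensus_pool import RankedList
from .deck_io import CompoundRecord, Pose
from .descriptor_filters import (
    DEFAULT_ALERTS,
    Stage1Thresholds,
    compute_descriptors,
    stage1_filter,
)
from .diversity_picker import Clustering
from .pharmacophore3d import (
    ExclusionSphere,
    PharmacophoreFeature,
    PharmacophoreModel,
    type_ligand_atoms,
)

__all__ = [
    "DeckSpec",
    "GenerationError",
    "gen_molecules",
    "gen_poses",
    "gen_ranked_lists",
    "gen_labels",
    "assign_stage2_properties",
    "plan_selection_ranking",
    "default_pharmacophore_model",
    "gen_funnel_inputs",
    "ENGINES",
]

ENGINES = (("chemscore", "higher"), ("asp", "higher"), ("glide_sp", "lower"))


class GenerationError(ValueError):
    """Requested plant is infeasible (quota, overlap, or geometry)."""


@dataclass
class DeckSpec:
    """Study conditions for one synthetic screen."""

    n_compounds: int = 3000
    seed: int = 0
    violation_quotas: dict[str, int] = field(
        default_factory=lambda: {
            "aromatic_rings": 8,
            "rotatable_bonds": 8,
            "hbd": 8,
            "clogp": 8,
            "tpsa": 8,
            "alert": 8,
        }
    )
    stage2_quota: int = 314
    hit_rate: float = 0.005
    top_n: int = 1000
    n_union: int = 2057
    pose_pass_fraction: float = 0.85
    pose_match_plan: dict[str, tuple[int, bool]] | None = None

    def __post_init__(self) -> None:
        if sum(self.violation_quotas.values()) > self.n_compounds:
            raise GenerationError("violation quotas exceed deck size")
        if not 0 <= self.hit_rate <= 1:
            raise GenerationError("hit_rate must be in [0, 1]")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named-stream splitter: independent child generator per stream name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode()) & 0x7FFFFFFF])
    )


# ---------------------------------------------------------------------------
# fragment grammar: clean (stage-1-passing) deck members
# ---------------------------------------------------------------------------

_HEADS = [
    "CS(=O)(=O)", "CCS(=O)(=O)", "CC(C)S(=O)(=O)", "C1CC1S(=O)(=O)",
    "FC(F)(F)S(=O)(=O)", "CN(C)S(=O)(=O)", "O=S(=O)(N1CCCC1)", "CC(=O)N",
    "CO", "N#C", "O=C1CCCN1", "CS(=O)(=O)C",
]
_RINGS = [
    "c1ccc(cc1)", "c1ccc(c(C)c1)", "c1ccc(c(F)c1)", "c1ccc(c(Cl)c1)",
    "c1ccc(c(OC)c1)",
]
_LINKERS = ["", "N", "O", "C"]
# core templates; {T} is replaced by "(tail)" or ""
_CORES = [
    "c1ncnc2sc{T}cc12",      # thieno[2,3-d]pyrimidin-4-yl
    "c1ncnc2cc{T}sc12",      # thieno[3,2-d] isomer
    "c1ncnc2cc{T}ccc12",     # quinazolin-4-yl
    "c1ccnc2sc{T}cc12",      # thieno[2,3-b]pyridin-4-yl
    "c1ncnc2n(C)nc{T}c12",   # N-methylpyrazolo[3,4-d]pyrimidin-4-yl
]
_TAILS = ["", "C", "CC", "F", "Cl", "C(C)C", "OC"]


def _grammar_smiles():
    """Deterministic enumeration of cap+linker+core(tail) SMILES."""
    for head, ring, linker, core, tail in itertools.product(
        _HEADS, _RINGS, _LINKERS, _CORES, _TAILS
    ):
        yield head + ring + linker + core.format(T=f"({tail})" if tail else "")


# ---------------------------------------------------------------------------
# violator families: each variant is built to trip exactly one rule
# ---------------------------------------------------------------------------

def _variants_aromatic_rings():
    # five azine rings chained: polar enough to stay under the clogP bound
    base = "c1ncc(-c2ncc(-c3ncc(-c4ncc(-c5ccnc{X}c5)cn4)cn3)cn2)c{Y}n1"
    for x in ["", "(C)", "(F)", "(Cl)", "(OC)", "(N)", "(CC)", "(O)"]:
        for y in ["", "(C)", "(F)", "(OC)"]:
            yield base.format(X=x, Y=y)


def _variants_rotatable_bonds():
    # PEG chains: many rotors, low logP, TPSA below the cut
    for units in (5, 6, 7, 8, 9):
        chain = "O" + "CCO" * units
        yield chain
        yield "C" + chain          # methyl-capped
        yield chain[:-1] + "OC"    # methyl ether end


def _variants_hbd():
    # polyols / aminopolyols: 4+ donors, everything else modest
    seeds = [
        "OCC(O)C(O)CO", "OCC(O)C(O)C(O)CO", "OCC(O)C(O)C(O)C(O)CO",
        "NCC(O)C(O)CO", "NCC(O)C(O)C(O)CO", "OCC(O)CC(O)CO",
        "OCC(O)C(C)(O)CO", "OC(CO)C(O)CO", "NC(CO)C(O)CO",
        "OCC(O)C(O)CNC", "OCC(N)C(O)CO", "OCCC(O)C(O)CO",
    ]
    yield from seeds


def _variants_clogp():
    # tri-tert-butylbenzene derivatives: lipophilic, rigid, apolar
    yield "CC(C)(C)c1cc(C(C)(C)C)cc(C(C)(C)C)c1"
    for x in ["C", "CC", "F", "Cl", "Br", "I", "C(C)C", "CCC", "CCCC", "C(C)(C)C"]:
        yield f"CC(C)(C)c1c({x})cc(C(C)(C)C)cc1C(C)(C)C"


def _variants_tpsa():
    # polynitroarenes: very high TPSA, no donors, low logP
    base = "O=[N+]([O-])c1cc(cc(c1{X})[N+](=O)[O-])[N+](=O)[O-]"
    for x in ["", "C", "F", "Cl", "OC", "CC", "Br", "N#C".replace("N#C", "C#N")]:
        yield base.format(X=f"{x}" if x else "")


def _variants_alert():
    # one reactive motif on an otherwise clean polar scaffold
    yield from [
        "ClC(=O)c1ccc(S(C)(=O)=O)cc1",       # acyl chloride
        "O=Cc1ccc(S(C)(=O)=O)cc1",           # aldehyde
        "ClS(=O)(=O)c1ccc(C)cc1",            # sulfonyl chloride
        "O=C1OC(=O)c2ccccc12",               # anhydride
        "ClC(=O)c1ccc(C#N)cc1",
        "O=Cc1ccc(C#N)cc1",
        "ClC(=O)c1ccncc1",
        "O=Cc1ccncc1",
        "ClS(=O)(=O)c1ccncc1",
        "O=Cc1ccc(F)cc1",
        "ClC(=O)c1ccc(F)cc1",
        "O=Cc1ccc(Cl)cc1",
    ]


_VIOLATOR_FAMILIES = {
    "aromatic_rings": _variants_aromatic_rings,
    "rotatable_bonds": _variants_rotatable_bonds,
    "hbd": _variants_hbd,
    "clogp": _variants_clogp,
    "tpsa": _variants_tpsa,
    "alert": _variants_alert,
}

_RULE_PREFIX = {
    "aromatic_rings": "aromatic_rings>",
    "rotatable_bonds": "rotatable_bonds>",
    "hbd": "hbd>",
    "clogp": "clogp>",
    "tpsa": "tpsa>",
    "alert": "alert:",
}


def gen_molecules(spec: DeckSpec) -> tuple[list[CompoundRecord], dict[str, dict]]:
    """Generate the deck: clean members plus exact per-rule violator quotas.

    Returns (records, truth) where ``truth[id]`` holds ``planted_rule``
    (None for clean members) and ``stage1_pass``. Every planted violator is
    verified at generation time to fire exactly its intended rule; every
    clean member is verified to pass stage 1. Deterministic per spec+seed.
    """
    rng = _rng(spec.seed, "molecules")
    thresholds = Stage1Thresholds()
    n_violators = sum(spec.violation_quotas.values())
    n_clean = spec.n_compounds - n_violators

    clean: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, smi in enumerate(_grammar_smiles()):
        if len(clean) == n_clean:
            break
        try:
            rec = CompoundRecord.from_smiles(f"tmp{i}", smi, source="synthetic")
        except ValueError:
            continue
        if rec.smiles in seen:
            continue
        verdict = stage1_filter([rec], [DEFAULT_ALERTS], thresholds)[0]
        if not verdict.passed:
            continue
        seen.add(rec.smiles)
        clean.append(rec)
    if len(clean) < n_clean:
        raise GenerationError(
            f"fragment grammar exhausted: {len(clean)} clean compounds < {n_clean}"
        )

    violators: list[tuple[CompoundRecord, str]] = []
    for rule, quota in spec.violation_quotas.items():
        if rule not in _VIOLATOR_FAMILIES:
            raise GenerationError(f"unknown violation rule {rule!r}")
        got = 0
        for j, smi in enumerate(_VIOLATOR_FAMILIES[rule]()):
            if got == quota:
                break
            try:
                rec = CompoundRecord.from_smiles(f"tmpv_{rule}_{j}", smi, source="synthetic")
            except ValueError:
                continue
            if rec.smiles in seen:
                continue
            verdict = stage1_filter([rec], [DEFAULT_ALERTS], thresholds)[0]
            fired = {_classify_reason(r) for r in verdict.reasons}
            if fired != {rule}:
                continue   # variant drifted; skip rather than mislabel
            seen.add(rec.smiles)
            violators.append((rec, rule))
            got += 1
        if got < quota:
            raise GenerationError(f"cannot plant {quota} violators of {rule!r} (got {got})")

    # interleave and relabel with stable ids
    members: list[tuple[CompoundRecord, str | None]] = [(r, None) for r in clean] + [
        (r, rule) for r, rule in violators
    ]
    perm = rng.permutation(len(members))
    records: list[CompoundRecord] = []
    truth: dict[str, dict] = {}
    width = len(str(len(members)))
    for new_idx, old_idx in enumerate(perm):
        rec, rule = members[old_idx]
        cid = f"SYN{new_idx:0{width}d}"
        rec = CompoundRecord(
            id=cid, smiles=rec.smiles, source_smiles=rec.source_smiles,
            source="synthetic", extra=dict(rec.extra),
        )
        records.append(rec)
        truth[cid] = {"planted_rule": rule, "stage1_pass": rule is None,
                      "smiles": rec.smiles}
    return records, truth


def _classify_reason(reason: str) -> str:
    for rule, prefix in _RULE_PREFIX.items():
        if reason.startswith(prefix):
            return rule
    return reason


# ---------------------------------------------------------------------------
# pharmacophore model and poses
# ---------------------------------------------------------------------------

def default_pharmacophore_model() -> PharmacophoreModel:
    """Synthetic stand-in for the 4-feature AMP-site model (2-of-4 logic).

    Two acceptor and two donor projection spheres of radius 1.4 Å at
    geometrically consistent but arbitrary centers, plus six exclusion
    spheres below the feature plane. The original model's centers derive
    from an unpublished protein frame, so any concrete coordinates are a
    synthetic construction.
    """
    r = 1.4
    return PharmacophoreModel(
        features=[
            PharmacophoreFeature("acceptor_site", (0.0, 0.0, 0.0), r),
            PharmacophoreFeature("acceptor_site", (8.0, 0.0, 0.0), r),
            PharmacophoreFeature("donor_site", (0.0, 8.0, 0.0), r),
            PharmacophoreFeature("donor_site", (8.0, 8.0, 0.0), r),
        ],
        min_required=2,
        exclusions=[
            ExclusionSphere((x, y, -6.0), r)
            for x in (0.0, 4.0, 8.0)
            for y in (0.0, 8.0)
        ],
    )


def _check_model_geometry(model: PharmacophoreModel) -> None:
    centers = [np.asarray(f.center) for f in model.features] + [
        np.asarray(e.center) for e in model.exclusions
    ]
    radii = [f.radius for f in model.features] + [e.radius for e in model.exclusions]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) <= radii[i] + radii[j]:
                raise GenerationError("pharmacophore spheres overlap; cannot plant poses")


def gen_poses(
    deck: list[CompoundRecord],
    model: PharmacophoreModel,
    plan: dict[str, tuple[int, bool]],
    seed: int = 0,
) -> list[Pose]:
    """Plant poses with requested matched-feature counts.

    ``plan[id] = (n_match, violate_exclusion)``: exactly ``n_match``
    features receive a complementary polar atom at radius × u (u ~ U(0,
    0.9)) from the center; when ``violate_exclusion`` one extra atom is
    placed inside the first exclusion sphere. All remaining atoms are
    placed at least 2 × radius away from every sphere.
    """
    _check_model_geometry(model)
    rng = _rng(seed, "poses")
    by_id = {rec.id: rec for rec in deck}
    poses: list[Pose] = []
    for cid, (n_match, violate) in plan.items():
        rec = by_id[cid]
        typing = type_ligand_atoms(rec)
        heavy_syms = [a.GetSymbol() for a in rec.mol.GetAtoms() if a.GetAtomicNum() != 1]
        coords = np.zeros((len(heavy_syms), 3))
        used: set[int] = set()

        acceptors = [i for i, t in enumerate(typing) if t in ("acceptor", "both")]
        donors = [i for i, t in enumerate(typing) if t in ("donor", "both")]
        # choose features to satisfy, preferring whichever pool is deeper
        chosen: list[tuple[int, int]] = []   # (feature index, atom index)
        feat_order = sorted(
            range(len(model.features)),
            key=lambda fi: model.features[fi].kind != "acceptor_site"
            if len(acceptors) >= len(donors) else model.features[fi].kind != "donor_site",
        )
        for fi in feat_order:
            if len(chosen) == n_match:
                break
            pool = acceptors if model.features[fi].kind == "acceptor_site" else donors
            atom = next((a for a in pool if a not in used), None)
            if atom is None:
                continue
            used.add(atom)
            chosen.append((fi, atom))
        if len(chosen) < n_match:
            raise GenerationError(
                f"{cid}: cannot plant {n_match} matches "
                f"({len(acceptors)} acceptors, {len(donors)} donors)"
            )
        for fi, atom in chosen:
            feat = model.features[fi]
            u = rng.uniform(0.0, 0.9)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            coords[atom] = np.asarray(feat.center) + feat.radius * u * v

        far_idx = [i for i in range(len(heavy_syms)) if i not in used]
        if violate:
            if not far_idx:
                raise GenerationError(f"{cid}: no spare atom for exclusion plant")
            atom = far_idx.pop(0)
            ex = model.exclusions[0]
            coords[atom] = np.asarray(ex.center) + np.array([0.3, 0.0, 0.0])
        # park the rest on a distant grid, trivially clear of every sphere
        for row, atom in enumerate(far_idx):
            coords[atom] = np.array([60.0 + 2.0 * row, 60.0, 60.0])
        poses.append(Pose(cid, heavy_syms, coords))
    return poses


def make_pose_plan(
    ids: list[str],
    min_required: int,
    pass_fraction: float,
    seed: int = 0,
) -> dict[str, tuple[int, bool]]:
    """Default pose plan: a planted fraction passes at ``min_required``
    matches; the rest split between too-few-matches and exclusion hits."""
    rng = _rng(seed, "pose_plan")
    n_pass = int(round(pass_fraction * len(ids)))
    order = list(rng.permutation(len(ids)))
    plan: dict[str, tuple[int, bool]] = {}
    for rank, idx in enumerate(order):
        cid = ids[idx]
        if rank < n_pass:
            plan[cid] = (min_required, False)
        elif rng.random() < 0.5:
            plan[cid] = (int(rng.integers(0, min_required)), False)
        else:
            plan[cid] = (min_required, True)   # matches but vetoed
    return plan


# ---------------------------------------------------------------------------
# ranked lists with exact top-N overlap structure
# ---------------------------------------------------------------------------

def _overlap_plan(top_n: int, n_union: int, n_engines: int = 3) -> tuple[int, int, int]:
    """Counts (x, y, z) of union members in 3 / 2 / 1 engines so that the
    union of three top-N prefixes has exactly ``n_union`` members."""
    if not top_n <= n_union <= n_engines * top_n:
        raise GenerationError(
            f"union {n_union} infeasible for {n_engines} lists of top {top_n}"
        )
    excess = n_engines * top_n - n_union      # = 2x + y
    x = min(excess // 2, n_union)
    y = excess - 2 * x
    z = n_union - x - y
    if z < 0 or y < 0:
        raise GenerationError(f"no feasible overlap plan for union {n_union}")
    return x, y, z


def gen_ranked_lists(
    ids: list[str],
    top_n: int,
    n_union: int,
    seed: int = 0,
    priority: list[str] | None = None,
) -> list[RankedList]:
    """Three engine lists whose top-N union has exactly ``n_union`` members.

    ``priority`` (default: a seeded shuffle of ``ids``) orders compounds
    within every engine's list, and its first ``n_union`` entries are the
    planted union. One engine is lower-better to exercise direction
    handling. Scores are distinct, so prefixes are unambiguous.
    """
    rng = _rng(seed, "ranked_lists")
    if priority is None:
        priority = [ids[i] for i in rng.permutation(len(ids))]
    if len(priority) < n_union:
        raise GenerationError("not enough compounds for the requested union")
    x, y, z = _overlap_plan(top_n, n_union, len(ENGINES))
    union = priority[:n_union]
    membership: dict[str, set[int]] = {}
    remaining = [top_n] * len(ENGINES)
    for cid in union[:x]:
        membership[cid] = {0, 1, 2}
    for e, cid in enumerate(union[x : x + y]):
        pair = [(0, 1), (1, 2), (0, 2)][e % 3]
        membership[cid] = set(pair)
    for cid in union[:x]:
        for e in membership[cid]:
            remaining[e] -= 1
    for cid in union[x : x + y]:
        for e in membership[cid]:
            remaining[e] -= 1
    singles = union[x + y :]
    assert len(singles) == z
    for cid in singles:
        e = int(np.argmax(remaining))
        if remaining[e] == 0:
            raise GenerationError("overlap plan ran out of engine capacity")
        membership[cid] = {e}
        remaining[e] -= 1
    if any(remaining):
        raise GenerationError(f"engine prefixes under-filled: {remaining}")

    prio_pos = {cid: i for i, cid in enumerate(priority)}
    lists: list[RankedList] = []
    for e, (engine, direction) in enumerate(ENGINES):
        top = sorted((cid for cid in union if e in membership[cid]),
                     key=lambda c: prio_pos[c])
        tail = sorted((cid for cid in priority if cid not in set(top)),
                      key=lambda c: prio_pos[c])
        ordered = top + tail
        n = len(ordered)
        if direction == "higher":
            entries = [(cid, float(n - i)) for i, cid in enumerate(ordered)]
        else:
            entries = [(cid, float(i + 1)) for i, cid in enumerate(ordered)]
        lists.append(RankedList(engine, entries, direction))
    return lists


# ---------------------------------------------------------------------------
# stage-2 property plant, labels, selection-ranking plan
# ---------------------------------------------------------------------------

def assign_stage2_properties(
    records: list[CompoundRecord],
    pool_ids: list[str],
    quota: int,
    seed: int = 0,
    max_logd: float = 5.0,
    max_psa: float = 100.0,
) -> set[str]:
    """Write caller-supplied-style logD/PSA columns into ``record.extra``.

    Exactly ``quota`` of the pool members get logD > ``max_logd`` AND
    PSA > ``max_psa``; every other compound stays inside at least one
    bound. Returns the planted violator id set.
    """
    if quota > len(pool_ids):
        raise GenerationError(f"stage-2 quota {quota} exceeds pool size {len(pool_ids)}")
    rng = _rng(seed, "stage2")
    violators = {pool_ids[i] for i in rng.permutation(len(pool_ids))[:quota]}
    for rec in records:
        if rec.id in violators:
            rec.extra["logd"] = float(max_logd + 0.2 + rng.uniform(0, 2.0))
            rec.extra["psa"] = float(max_psa + 2.0 + rng.uniform(0, 30.0))
        elif rng.random() < 0.5:
            rec.extra["logd"] = float(rng.uniform(-1.0, max_logd - 0.1))
            rec.extra["psa"] = float(rng.uniform(20.0, max_psa + 40.0))
        else:
            rec.extra["logd"] = float(rng.uniform(-1.0, max_logd + 2.0))
            rec.extra["psa"] = float(rng.uniform(20.0, max_psa - 0.5))
    return violators


def gen_labels(ids: list[str], hit_rate: float, seed: int = 0) -> dict[str, int]:
    """Independent Bernoulli(hit_rate) activity label per compound."""
    if not 0 <= hit_rate <= 1:
        raise GenerationError("hit_rate must be in [0, 1]")
    rng = _rng(seed, "labels")
    return {cid: int(rng.random() < hit_rate) for cid in ids}


def plan_selection_ranking(
    clustering: Clustering,
    top_m: int = 50,
    n_shadowed: int = 21,
    seed: int = 0,
) -> list[str]:
    """Ranking over clustered compounds planting an exact trim count.

    Places ``top_m − n_shadowed`` cluster representatives at the head,
    followed by ``n_shadowed`` compounds sharing a cluster with one of
    them. Selection with this ranking then augments the cluster
    representatives by exactly ``n_shadowed`` top-M additions, so exactly
    ``n_shadowed`` compounds are trimmed back to the cluster-count target.
    """
    if n_shadowed > top_m:
        raise GenerationError("n_shadowed cannot exceed top_m")
    rng = _rng(seed, "selection_plan")
    clusters = clustering.clusters_by_id()
    multi = sorted(mid for mid, members in clusters.items() if len(members) >= 2)
    if len(multi) < n_shadowed:
        raise GenerationError(
            f"only {len(multi)} multi-member clusters; need {n_shadowed}"
        )
    n_lead = top_m - n_shadowed
    if len(clusters) < n_lead:
        raise GenerationError("fewer clusters than leading ranking slots")
    shadow_clusters = multi[:n_shadowed]
    other_clusters = [mid for mid in sorted(clusters) if mid not in set(shadow_clusters)]

    leaders: list[str] = []
    shadows: list[str] = []
    for mid in shadow_clusters:
        members = sorted(clusters[mid])
        leaders.append(members[0])
        shadows.append(members[1])
    for mid in other_clusters:
        if len(leaders) == n_lead:
            break
        leaders.append(sorted(clusters[mid])[0])
    if len(leaders) < n_lead:
        raise GenerationError("not enough clusters to fill the ranking head")
    head = leaders[:n_lead] + shadows
    placed = set(head)
    rest = [cid for members in clusters.values() for cid in members if cid not in placed]
    rest = [rest[i] for i in rng.permutation(len(rest))]
    return head + rest


# ---------------------------------------------------------------------------
# composite generator mirroring the full funnel
# ---------------------------------------------------------------------------

def gen_funnel_inputs(spec: DeckSpec, with_poses: bool = True) -> dict:
    """All inputs for one coherent synthetic screen.

    Returns a dict with records, truth, model, pose plan and poses (for
    the stage-1 passers), ranked lists over the pharmacophore passers,
    stage-2 violator ids, and activity labels.
    """
    records, truth = gen_molecules(spec)
    stage1_pass = [r.id for r in records if truth[r.id]["stage1_pass"]]
    model = default_pharmacophore_model()

    plan = spec.pose_match_plan or make_pose_plan(
        stage1_pass, model.min_required, spec.pose_pass_fraction, spec.seed
    )
    pharm_pass = sorted(
        cid for cid, (n, violate) in plan.items()
        if n >= model.min_required and not violate
    )
    poses = gen_poses(
        [r for r in records if r.id in plan], model, plan, spec.seed
    ) if with_poses else []

    if len(pharm_pass) < spec.n_union:
        raise GenerationError(
            f"{len(pharm_pass)} pharmacophore passers < union target {spec.n_union}"
        )
    lists = gen_ranked_lists(pharm_pass, spec.top_n, spec.n_union, spec.seed)
    from .consensus_pool import pool as _pool

    members = sorted(_pool(lists, spec.top_n).members)
    stage2_violators = assign_stage2_properties(
        records, members, spec.stage2_quota, spec.seed
    )
    labels = gen_labels([r.id for r in records], spec.hit_rate, spec.seed)
    return {
        "records": records,
        "truth": truth,
        "model": model,
        "pose_plan": plan,
        "poses": poses,
        "pharm_pass": pharm_pass,
        "ranked_lists": lists,
        "pool_members": members,
        "stage2_violators": stage2_violators,
        "labels": labels,
    }
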