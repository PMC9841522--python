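"""3D pharmacophore pose filtering with projected feature and exclusion spheres.

The model mirrors an ATP/AMP-site pharmacophore built from a kinase
structure: projected **acceptor sites** (spheres where a ligand
hydrogen-bond acceptor should sit, opposite a protein donor) and
**donor sites** (spheres hosting a ligand donor), each of radius 1.4 Å
by default, with an ``m-of-n`` match requirement (2 of 4 in the screen
this package mirrors) and exclusion spheres on the remaining pocket
atoms. A pose passes when at least ``min_required`` features each
contain a complementary ligand heavy atom and no ligand heavy atom lies
inside any exclusion sphere. Distances exactly equal to a radius count
as inside.

Only heavy atoms are tested; polar hydrogens are folded into the donor
typing of their parent N/O, so poses without explicit hydrogens are
handled uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .deck_io import CompoundRecord, Pose

__all__ = [
    "PharmacophoreFeature",
    "ExclusionSphere",
    "PharmacophoreModel",
    "MatchResult",
    "AlignmentError",
    "MatchError",
    "type_ligand_atoms",
    "match",
    "screen_poses",
]

SCHEMA_VERSION = 1

FEATURE_KINDS = ("acceptor_site", "donor_site")


class AlignmentError(ValueError):
    """Pose and structure atom orders cannot be reconciled."""


class MatchError(ValueError):
    """Pose unusable for matching (e.g. empty)."""


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple[float, float, float]
    radius: float = 1.4

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature kind must be one of {FEATURE_KINDS}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class ExclusionSphere:
    center: tuple[float, float, float]
    radius: float = 1.4

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    min_required: int
    exclusions: list[ExclusionSphere] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.min_required <= len(self.features)):
            raise ValueError("0 <= min_required <= number of features required")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "PharmacophoreModel":
        """Model with every center mapped through x -> R @ x + t."""
        R = np.asarray(R, float)
        t = np.asarray(t, float)
        return PharmacophoreModel(
            [PharmacophoreFeature(f.kind, tuple(R @ np.asarray(f.center) + t), f.radius)
             for f in self.features],
            self.min_required,
            [ExclusionSphere(tuple(R @ np.asarray(e.center) + t), e.radius)
             for e in self.exclusions],
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "min_required": self.min_required,
            "features": [
                {"kind": f.kind, "center": list(f.center), "radius": f.radius}
                for f in self.features
            ],
            "exclusions": [
                {"center": list(e.center), "radius": e.radius} for e in self.exclusions
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PharmacophoreModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported pharmacophore schema: {doc.get('schema_version')}")
        return cls(
            [PharmacophoreFeature(f["kind"], tuple(f["center"]), f.get("radius", 1.4))
             for f in doc["features"]],
            doc["min_required"],
            [ExclusionSphere(tuple(e["center"]), e.get("radius", 1.4))
             for e in doc.get("exclusions", [])],
        )


@dataclass(frozen=True)
class MatchResult:
    compound_id: str
    matched_features: frozenset[int]
    exclusion_hits: tuple[tuple[int, int], ...]   # (atom index, sphere index)
    passed: bool
    matched_distance: float = 0.0   # summed atom-to-center distance over matched features


# amide N excluded from acceptors; positively charged N/O excluded
_AMIDE_N = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")


def type_ligand_atoms(record: CompoundRecord) -> list[str]:
    """Per-heavy-atom donor/acceptor typing from the 2D structure.

    Rules: acceptor = N or O with a lone pair and no positive formal charge,
    excluding amide nitrogens; donor = N or O bearing >= 1 hydrogen
    (implicit or explicit). Returns one of ``acceptor``, ``donor``,
    ``both``, ``neither`` per heavy atom, in structure atom order.
    """
    mol = record.mol
    if mol is None:
        raise ValueError(f"{record.id}: invalid structure")
    amide_n = {m[0] for m in mol.GetSubstructMatches(_AMIDE_N)}
    typing: list[str] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        sym = atom.GetSymbol()
        donor = sym in ("N", "O") and atom.GetTotalNumHs() >= 1
        acceptor = (
            sym in ("N", "O")
            and atom.GetFormalCharge() <= 0
            and atom.GetIdx() not in amide_n
        )
        if donor and acceptor:
            typing.append("both")
        elif donor:
            typing.append("donor")
        elif acceptor:
            typing.append("acceptor")
        else:
            typing.append("neither")
    return typing


_COMPLEMENT = {"acceptor_site": ("acceptor", "both"), "donor_site": ("donor", "both")}


def match(pose: Pose, typing: list[str], model: PharmacophoreModel) -> MatchResult:
    """Evaluate one pose against the model.

    Feature i is matched iff some ligand heavy atom of the complementary
    type lies within (<=) the feature radius of its center; any heavy atom
    within an exclusion sphere vetoes the pose.
    """
    keep = [i for i, e in enumerate(pose.elements) if e != "H"]
    if not keep:
        raise MatchError(f"{pose.compound_id}: empty pose (no heavy atoms)")
    if len(keep) != len(typing):
        raise AlignmentError(
            f"{pose.compound_id}: pose has {len(keep)} heavy atoms, "
            f"typing has {len(typing)}"
        )

    coords = pose.coords[keep]
    matched: set[int] = set()
    total_dist = 0.0
    if model.features:
        centers = np.array([f.center for f in model.features], float)
        D = cdist(coords, centers)
        for i, feat in enumerate(model.features):
            ok_types = _COMPLEMENT[feat.kind]
            idx = [a for a, t in enumerate(typing) if t in ok_types]
            if idx:
                dmin = D[idx, i].min()
                if dmin <= feat.radius:
                    matched.add(i)
                    total_dist += float(dmin)

    hits: list[tuple[int, int]] = []
    if model.exclusions:
        ex_centers = np.array([e.center for e in model.exclusions], float)
        ex_radii = np.array([e.radius for e in model.exclusions], float)
        E = cdist(coords, ex_centers)
        for a, s in zip(*np.nonzero(E <= ex_radii[None, :])):
            hits.append((int(a), int(s)))

    passed = len(matched) >= model.min_required and not hits
    return MatchResult(
        compound_id=pose.compound_id,
        matched_features=frozenset(matched),
        exclusion_hits=tuple(hits),
        passed=passed,
        matched_distance=total_dist,
    )


def screen_poses(
    poses: list[Pose],
    typings: dict[str, list[str]],
    model: PharmacophoreModel,
    keep_best_per_compound: bool = True,
) -> tuple[list[str], list[dict], dict[str, MatchResult]]:
    """Screen many poses (possibly several per compound).

    A compound passes if ANY of its poses passes. The best pose per
    compound has the most matched features, ties broken by smallest summed
    atom-to-center distance over matched features, then by first pose index.

    Returns (sorted pass id list, per-pose result rows, best result per
    compound).
    """
    rows: list[dict] = []
    best: dict[str, tuple[tuple, MatchResult]] = {}
    passed_ids: set[str] = set()
    for idx, pose in enumerate(poses):
        res = match(pose, typings[pose.compound_id], model)
        rows.append({
            "compound_id": res.compound_id,
            "pose_index": idx,
            "n_matched": len(res.matched_features),
            "matched_features": ";".join(map(str, sorted(res.matched_features))),
            "n_exclusion_hits": len(res.exclusion_hits),
            "passed": res.passed,
        })
        if res.passed:
            passed_ids.add(res.compound_id)
        key = (-len(res.matched_features), res.matched_distance, idx)
        if keep_best_per_compound:
            prev = best.get(res.compound_id)
            if prev is None or key < prev[0]:
                best[res.compound_id] = (key, res)
    return sorted(passed_ids), rows, {cid: r for cid, (_, r) in best.items()}
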