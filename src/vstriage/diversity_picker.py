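"""Diversity-driven purchase-set assembly.

Pipeline: Morgan circular fingerprints (default radius 4, 2048 bits, as
in the screen this package mirrors — note many tools call the common
ECFP4 setting radius 2), Tanimoto distances (1 − similarity), PAM
k-medoids clustering, then the representative + top-M + trim selection
rule: take the best-ranked member of each cluster, add any global
top-M compounds not already selected, and remove the worst-ranked
compounds until the target size is reached.

The PAM implementation is BUILD followed by best-improvement SWAP until
no improving swap exists, vectorized over the full distance matrix, and
deterministic for a given seed and input order (the seed only breaks
exact ties in BUILD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .deck_io import CompoundRecord

__all__ = [
    "FingerprintVector",
    "Clustering",
    "SelectionReport",
    "FingerprintError",
    "fingerprint",
    "tanimoto",
    "tanimoto_distance_matrix",
    "kmedoids",
    "select_purchase_set",
]


class FingerprintError(ValueError):
    """Fingerprinting failed for a structure."""


@dataclass(frozen=True)
class FingerprintVector:
    compound_id: str
    bits: frozenset[int]
    radius: int
    nbits: int

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit indices out of range")


def fingerprint(record: CompoundRecord, radius: int = 4, nbits: int = 2048) -> FingerprintVector:
    """Hashed Morgan circular fingerprint of one compound.

    Deterministic; structures with equal canonical SMILES give identical
    vectors. Hash collisions at ``nbits`` are accepted, as is standard.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mol = record.mol
    if mol is None:
        raise FingerprintError(f"{record.id}: structure failed to sanitize")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return FingerprintVector(record.id, frozenset(bv.GetOnBits()), radius, nbits)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """|a∩b| / |a∪b|; two empty vectors are identical (similarity 1)."""
    if a.nbits != b.nbits:
        raise ValueError(f"nbits mismatch: {a.nbits} vs {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def _to_bitvect(fp: FingerprintVector):
    bv = DataStructs.ExplicitBitVect(fp.nbits)
    for b in fp.bits:
        bv.SetBit(b)
    return bv


def tanimoto_distance_matrix(fps: list[FingerprintVector]) -> np.ndarray:
    """Symmetric (1 − Tanimoto) matrix with zero diagonal."""
    n = len(fps)
    bvs = [_to_bitvect(fp) for fp in fps]
    D = np.zeros((n, n))
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(bvs[i], bvs[:i])
        D[i, :i] = 1.0 - np.asarray(sims)
    D += D.T
    # empty-vs-empty: RDKit reports similarity 0; we define identical empties
    empties = [i for i, fp in enumerate(fps) if not fp.bits]
    for i in empties:
        for j in empties:
            D[i, j] = 0.0
    return D


@dataclass
class Clustering:
    """PAM output: medoid indices, per-point assignment, total cost."""

    k: int
    medoids: list[int]
    assignment: np.ndarray                 # index -> medoid index (dataset indexing)
    cost: float
    cost_history: list[float] = field(default_factory=list)
    ids: list[str] | None = None

    @property
    def medoid_ids(self) -> list[str]:
        if self.ids is None:
            raise ValueError("clustering has no id mapping")
        return [self.ids[m] for m in self.medoids]

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {m: [] for m in self.medoids}
        for i, m in enumerate(self.assignment):
            out[int(m)].append(i)
        return out

    def clusters_by_id(self) -> dict[str, list[str]]:
        if self.ids is None:
            raise ValueError("clustering has no id mapping")
        return {
            self.ids[m]: [self.ids[i] for i in members]
            for m, members in self.clusters().items()
        }


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if (D < 0).any() or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric and non-negative")
    return D


def _build(D: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """Greedy BUILD initialization; seed breaks exact gain ties."""
    n = D.shape[0]
    totals = D.sum(axis=1)
    first_candidates = np.flatnonzero(totals == totals.min())
    medoids = [int(rng.choice(first_candidates))]
    dn = D[:, medoids[0]].copy()
    chosen = np.zeros(n, dtype=bool)
    chosen[medoids[0]] = True
    while len(medoids) < k:
        gains = np.maximum(dn[:, None] - D, 0.0).sum(axis=0)
        gains[chosen] = -np.inf
        best_candidates = np.flatnonzero(gains == gains.max())
        best = int(rng.choice(best_candidates))
        medoids.append(best)
        chosen[best] = True
        np.minimum(dn, D[:, best], out=dn)
    return medoids


def _nearest(D: np.ndarray, medoids: np.ndarray):
    """Nearest/second-nearest medoid distances and nearest medoid column.

    Ties go to the smaller medoid index (medoids kept sorted ascending)."""
    dm = D[:, medoids]                     # n × k
    j1 = np.argmin(dm, axis=1)             # first occurrence = smallest medoid
    dn = dm[np.arange(len(D)), j1]
    dm2 = dm.copy()
    dm2[np.arange(len(D)), j1] = np.inf
    ds = dm2.min(axis=1)
    return dn, ds, j1


def kmedoids(D: np.ndarray, k: int, seed: int = 0) -> Clustering:
    """PAM k-medoids on a precomputed distance matrix.

    BUILD initialization then best-improvement SWAP iterations until no
    swap lowers the summed distance to assigned medoids. The cost history
    (one entry per accepted configuration) is strictly non-increasing.
    """
    D = _validate_distance_matrix(D)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    medoids = np.array(sorted(_build(D, k, rng)))
    history: list[float] = []

    while True:
        dn, ds, j1 = _nearest(D, medoids)
        history.append(float(dn.sum()))
        if k == n:
            break
        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        cand = np.flatnonzero(~is_medoid)

        Dc = D[:, cand]                            # n × c
        low = np.minimum(Dc - dn[:, None], 0.0)
        delta_base = low.sum(axis=0)               # per candidate
        # correction per (medoid being removed, candidate): for points whose
        # nearest medoid is removed, the retained option is min(d(o,j), ds[o])
        g = np.minimum(Dc, ds[:, None]) - dn[:, None] - low
        order = np.argsort(j1, kind="stable")
        sorted_j1 = j1[order]
        starts = np.searchsorted(sorted_j1, np.arange(k))
        ends = np.searchsorted(sorted_j1, np.arange(k) + 1)
        csum = np.vstack([np.zeros((1, len(cand))), np.cumsum(g[order], axis=0)])
        M = csum[ends] - csum[starts]              # segment sums; empty clusters -> 0
        delta = delta_base[None, :] + M            # k × c
        i, j = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[i, j] >= -1e-12:
            break
        new = medoids.copy()
        new[i] = cand[j]
        medoids = np.sort(new)

    dn, _, j1 = _nearest(D, medoids)
    assignment = medoids[j1]
    return Clustering(
        k=k,
        medoids=[int(m) for m in medoids],
        assignment=assignment,
        cost=float(dn.sum()),
        cost_history=history + [float(dn.sum())],
    )


@dataclass
class SelectionReport:
    chosen: list[str]                     # final purchase set, best rank first
    reason: dict[str, str]                # id -> "cluster_best" | "topM_added"
    trimmed: list[str]                    # removed at the end, worst-ranked first


def select_purchase_set(
    clustering: Clustering,
    ranking: list[str],
    target: int,
    top_m: int = 50,
) -> SelectionReport:
    """Representative + top-M + trim selection.

    1. Take the best-ranked member of each cluster (``cluster_best``).
    2. Add every member of the global top ``top_m`` not already selected
       (``topM_added``).
    3. While the set exceeds ``target``, remove the worst-ranked selected
       compound (recorded in ``trimmed``, worst first).

    ``ranking`` must totally order all clustered compounds, best first.
    """
    if clustering.ids is None:
        raise ValueError("clustering must carry compound ids")
    pos = {cid: i for i, cid in enumerate(ranking)}
    clusters = clustering.clusters_by_id()
    all_members = [cid for members in clusters.values() for cid in members]
    missing = [cid for cid in all_members if cid not in pos]
    if missing:
        raise ValueError(f"ranking does not cover clustered compounds, e.g. {missing[:3]}")
    if target > len(clusters) + top_m:
        raise ValueError(
            f"target {target} infeasible for {len(clusters)} clusters + top {top_m}"
        )

    reason: dict[str, str] = {}
    for members in clusters.values():
        best = min(members, key=lambda cid: pos[cid])
        reason[best] = "cluster_best"
    ranked_members = sorted(all_members, key=lambda cid: pos[cid])
    for cid in ranked_members[:top_m]:
        if cid not in reason:
            reason[cid] = "topM_added"

    chosen = sorted(reason, key=lambda cid: pos[cid])
    if len(chosen) < target:
        raise ValueError(
            f"only {len(chosen)} selectable compounds for target {target}"
        )
    trimmed: list[str] = []
    while len(chosen) > target:
        worst = chosen.pop()
        trimmed.append(worst)
        del reason[worst]
    return SelectionReport(chosen=chosen, reason=reason, trimmed=trimmed)
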