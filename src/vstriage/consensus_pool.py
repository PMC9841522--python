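"""Consensus pooling of ranked docking outputs.

Several scoring functions score the same candidates on incommensurable
scales (e.g. two GOLD fitness functions and a Glide docking score, one of
which is lower-better). Rather than calibrating raw scores, the pool is
the union of each engine's top-N prefix, and candidates are ordered by a
scale-free positional-rank key: best rank across engines, then mean rank
over the engines where the candidate appears, then compound id. The rank
rule is pluggable via ``key_fn``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RankedList",
    "ConsensusPool",
    "InputError",
    "top_n",
    "pool",
    "global_rank",
]


class InputError(ValueError):
    """Malformed ranked-list input (duplicate ids, bad direction...)."""


@dataclass
class RankedList:
    """One engine's ordered output: (compound_id, score) best-first."""

    engine: str
    entries: list[tuple[str, float]]
    direction: str = "higher"   # "higher" (better) or "lower"

    def __post_init__(self) -> None:
        if not self.engine:
            raise InputError("engine name must be non-empty")
        if self.direction not in ("higher", "lower"):
            raise InputError("direction must be 'higher' or 'lower'")
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)
            dup = sorted(dup[dup.duplicated()].unique())
            raise InputError(f"duplicate compound ids in {self.engine}: {dup[:5]}")
        scores = [s for _, s in self.entries]
        ordered = all(a >= b for a, b in zip(scores, scores[1:])) if self.direction == "higher" \
            else all(a <= b for a, b in zip(scores, scores[1:]))
        if not ordered:
            raise InputError(f"{self.engine}: entries not sorted consistent with direction")

    @classmethod
    def from_scores(cls, engine: str, scores: dict[str, float], direction: str = "higher") -> "RankedList":
        """Build a ranked list from an id->score map; score ties break by id."""
        rev = direction == "higher"
        entries = sorted(scores.items(), key=lambda kv: (-kv[1] if rev else kv[1], kv[0]))
        return cls(engine, entries, direction)

    @classmethod
    def from_csv(cls, path, direction: str = "higher", engine: str | None = None) -> "RankedList":
        """Read an (engine, id, score) CSV; entries are re-sorted by score."""
        df = pd.read_csv(path, dtype={"id": str})
        eng = engine or str(df["engine"].iloc[0])
        return cls.from_scores(eng, dict(zip(df["id"], df["score"].astype(float))), direction)

    def positions(self) -> dict[str, int]:
        """1-based positional rank per compound."""
        return {cid: i + 1 for i, (cid, _) in enumerate(self.entries)}


@dataclass
class ConsensusPool:
    members: set[str]
    provenance: dict[str, set[str]]          # id -> engines that contributed it
    global_rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid in self.members:
            if not self.provenance.get(cid):
                raise InputError(f"pool member {cid} has no contributing engine")


def top_n(ranked: RankedList, n: int) -> RankedList:
    """First min(n, len) entries. Score ties at the cut are broken by
    ascending compound id (lists built via ``from_scores`` already are)."""
    if n < 0:
        raise InputError("n must be >= 0")
    entries = list(ranked.entries)
    # enforce the deterministic tie order before slicing
    rev = ranked.direction == "higher"
    entries.sort(key=lambda kv: (-kv[1] if rev else kv[1], kv[0]))
    return RankedList(ranked.engine, entries[:n], ranked.direction)


def pool(lists: list[RankedList], n: int) -> ConsensusPool:
    """Union of the engines' top-``n`` prefixes with per-id provenance."""
    if not lists:
        raise InputError("at least one ranked list required")
    members: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for rl in lists:
        for cid, _ in top_n(rl, n).entries:
            members.add(cid)
            provenance.setdefault(cid, set()).add(rl.engine)
    p = ConsensusPool(members=members, provenance=provenance)
    p.global_rank = {cid: i + 1 for i, cid in enumerate(global_rank(p, lists))}
    return p


def default_rank_key(cid: str, positions: list[dict[str, int]]):
    """(best positional rank, mean positional rank where present, id)."""
    present = [pos[cid] for pos in positions if cid in pos]
    if not present:
        raise InputError(f"pool member {cid} appears in no ranked list")
    return (min(present), sum(present) / len(present), cid)


def global_rank(p: ConsensusPool, lists: list[RankedList], key_fn=default_rank_key) -> list[str]:
    """Total deterministic order over pool members, best first."""
    positions = [rl.positions() for rl in lists]
    return sorted(p.members, key=lambda cid: key_fn(cid, positions))
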