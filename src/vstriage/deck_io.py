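"""Deck and pose I/O: SMILES/CSV compound tables, SDF pose files, CSV reports.

All readers are total: a syntactically broken record is logged and skipped,
never fatal. Output ordering is deterministic (sorted by compound id) so
identical inputs give byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

log = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "Pose",
    "ConfigurationError",
    "read_smiles_table",
    "read_pose_sdf",
    "write_pose_sdf",
    "write_report",
]


class ConfigurationError(ValueError):
    """Missing column, bad path, or otherwise unusable caller configuration."""


@dataclass
class CompoundRecord:
    """One deck member: id, structure, optional cached descriptors.

    The SMILES is canonicalized at ingest so duplicate detection is
    structure-based; the original string is retained in ``source_smiles``.
    """

    id: str
    smiles: str                      # canonical form
    source_smiles: str = ""
    source: str = ""
    descriptors: dict | None = None
    extra: dict = field(default_factory=dict)  # passthrough columns (e.g. logd, psa)

    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles)
        return self._mol

    @classmethod
    def from_smiles(cls, id: str, smiles: str, source: str = "", **extra) -> "CompoundRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES for {id!r}: {smiles!r}")
        rec = cls(
            id=str(id),
            smiles=Chem.MolToSmiles(mol),
            source_smiles=smiles,
            source=source,
            extra=extra,
        )
        rec._mol = mol
        return rec


@dataclass
class Pose:
    """A docked 3D pose: ordered atoms with coordinates plus engine scores.

    ``engine_scores`` maps engine name to raw score; score direction
    (higher- or lower-better) is carried separately by the consensus layer.
    """

    compound_id: str
    elements: list[str]
    coords: np.ndarray              # (n_atoms, 3), Å
    engine_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) < 1:
            raise ValueError("pose must have >= 1 atom")
        if self.coords.shape != (len(self.elements), 3) or not np.isfinite(self.coords).all():
            raise ValueError("pose coordinates must be finite (n_atoms, 3)")

    def heavy(self) -> "Pose":
        """Copy restricted to non-hydrogen atoms."""
        keep = [i for i, e in enumerate(self.elements) if e != "H"]
        return Pose(
            self.compound_id,
            [self.elements[i] for i in keep],
            self.coords[keep],
            dict(self.engine_scores),
        )


def read_smiles_table(
    path: str | Path,
    id_column: str = "id",
    smiles_column: str = "smiles",
    source: str | None = None,
) -> tuple[list[CompoundRecord], int]:
    """Read a CSV/TSV compound table. Returns (records, n_skipped).

    Rows whose SMILES fail to parse are logged with their row number and
    skipped. Extra columns are carried along in ``record.extra``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={id_column: str}, encoding="utf-8")
    for col in (id_column, smiles_column):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    other_cols = [c for c in df.columns if c not in (id_column, smiles_column)]
    records: list[CompoundRecord] = []
    skipped = 0
    for rownum, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rd = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        smi = rd[smiles_column]
        mol = Chem.MolFromSmiles(str(smi)) if pd.notna(smi) else None
        if mol is None:
            log.warning("%s row %d: invalid SMILES %r, skipped", path.name, rownum, smi)
            skipped += 1
            continue
        rec = CompoundRecord(
            id=str(rd[id_column]),
            smiles=Chem.MolToSmiles(mol),
            source_smiles=str(smi),
            source=source or path.name,
            extra={c: rd[c] for c in other_cols},
        )
        rec._mol = mol
        records.append(rec)
    return records, skipped


def read_pose_sdf(
    path: str | Path,
    score_tags: dict[str, str] | None = None,
) -> list[Pose]:
    """Read docked poses from an SDF file.

    ``score_tags`` maps engine name -> SDF property name. A record missing a
    tag yields a pose without that engine plus a warning; an unreadable
    molblock is skipped with a diagnostic.
    """
    score_tags = score_tags or {}
    poses: list[Pose] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("%s record %d: unreadable molblock, skipped", path, i)
            continue
        try:
            conf = mol.GetConformer()
        except ValueError:
            log.warning("%s record %d: no conformer, skipped", path, i)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"
        scores: dict[str, float] = {}
        for engine, tag in score_tags.items():
            if mol.HasProp(tag):
                try:
                    scores[engine] = float(mol.GetProp(tag))
                except ValueError:
                    log.warning("%s record %d: non-numeric %s, engine %s dropped",
                                path, i, tag, engine)
            else:
                log.warning("%s record %d (%s): missing score tag %r for engine %s",
                            path, i, name, tag, engine)
        poses.append(Pose(
            compound_id=name,
            elements=[a.GetSymbol() for a in mol.GetAtoms()],
            coords=conf.GetPositions(),
            engine_scores=scores,
        ))
    return poses


def write_pose_sdf(
    path: str | Path,
    poses: list[Pose],
    score_tags: dict[str, str] | None = None,
) -> None:
    """Write poses as a V2000 SDF (coordinates kept to 4 decimals by format)."""
    score_tags = score_tags or {}
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            rw = Chem.RWMol()
            for el in pose.elements:
                a = Chem.Atom(el)
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            conf = Chem.Conformer(len(pose.elements))
            for i, (x, y, z) in enumerate(pose.coords):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", pose.compound_id)
            for engine, score in pose.engine_scores.items():
                tag = score_tags.get(engine, engine)
                mol.SetProp(tag, repr(float(score)))
            writer.write(mol)
    finally:
        writer.close()


def write_report(
    path: str | Path,
    rows,
    id_column: str = "compound_id",
    columns: list[str] | None = None,
) -> None:
    """Write a CSV report with a header row, sorted by id, UTF-8 encoded.

    ``columns`` fixes the header (useful for an empty row list, which still
    produces a header-only file).
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows), columns=columns)
    if len(df) and id_column in df.columns:
        df = df.sort_values(id_column, kind="mergesort")
    df.to_csv(path, index=False, encoding="utf-8")
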