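"""Two-stage library triage: property descriptors and substructure alerts.

Stage 1 removes compounds flagged by substructure alerts (PAINS-like and
reactive motifs) or exceeding any of five property thresholds:
>4 aromatic rings, >10 rotatable bonds, >3 hydrogen-bond donors,
clogP > 5, TPSA > 125 Å².  Inequalities are strict: a compound with
exactly 4 aromatic rings passes.

Stage 2 is applied after consensus pooling and removes compounds with
logD > 5 and PSA > 100 Å².  The combination logic is configurable:
the default AND removes only compounds exceeding both bounds; an OR
mode removes compounds exceeding either.

logD at pH 7.4 is normally a caller-supplied column (the original values
come from vendor calculators).  The built-in surrogate — clogP minus a
fixed penalty per ionizable group — is a deliberately simple estimator
for testing and does not reproduce any vendor predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

from .deck_io import CompoundRecord

__all__ = [
    "DescriptorSet",
    "FilterVerdict",
    "AlertSet",
    "Stage1Thresholds",
    "Stage2Thresholds",
    "DescriptorError",
    "DEFAULT_ALERTS",
    "compute_descriptors",
    "stage1_filter",
    "stage2_filter",
]


class DescriptorError(ValueError):
    """Descriptor computation failed (carries the compound id)."""


@dataclass(frozen=True)
class DescriptorSet:
    aromatic_rings: int
    rotatable_bonds: int
    hbd: int
    clogp: float
    tpsa: float           # Å²
    logd: float           # pH 7.4 surrogate unless caller-supplied
    psa: float            # Å²; equals TPSA unless caller-supplied
    heavy_atoms: int

    def __post_init__(self) -> None:
        if min(self.aromatic_rings, self.rotatable_bonds, self.hbd) < 0:
            raise ValueError("counts must be >= 0")
        if self.tpsa < 0 or self.heavy_atoms < 1:
            raise ValueError("tpsa >= 0 and heavy_atoms >= 1 required")


@dataclass(frozen=True)
class FilterVerdict:
    compound_id: str
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when no reasons fired")


@dataclass
class AlertSet:
    """A named list of (label, SMARTS) substructure alerts."""

    name: str
    patterns: list[tuple[str, str]]
    _compiled: list[tuple[str, Chem.Mol]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._compiled = []
        for label, smarts in self.patterns:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise ValueError(f"alert {self.name}/{label}: SMARTS does not compile: {smarts!r}")
            self._compiled.append((label, q))

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "AlertSet":
        """Load a two-column (label, SMARTS) CSV with a header row."""
        import pandas as pd

        df = pd.read_csv(path)
        label_col, smarts_col = df.columns[:2]
        return cls(name or str(path), list(zip(df[label_col].astype(str), df[smarts_col].astype(str))))

    def hits(self, mol: Chem.Mol) -> list[str]:
        return [label for label, q in self._compiled if mol.HasSubstructMatch(q)]


# Small curated default alert set covering common PAINS-like and reactive
# motifs. Full published alert lists can be loaded from external SMARTS CSVs;
# this default makes no claim to reproduce any particular published list.
DEFAULT_ALERTS = AlertSet(
    "default",
    [
        ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
        ("sulfonyl_halide", "[SX4](=O)(=O)[F,Cl,Br,I]"),
        ("aldehyde", "[CX3H1](=O)[#6]"),
        ("michael_acceptor", "[CX3]=[CX3][CX3]=[OX1]"),
        ("epoxide_aziridine", "[OX2r3,NX3r3]1[#6r3][#6r3]1"),
        ("isocyanate", "[NX2]=[CX2]=[OX1]"),
        ("anhydride", "[CX3](=O)[OX2][CX3](=O)"),
        ("azide", "[NX2]=[NX2+]=[NX1-]"),
        ("alkyl_halide_primary", "[CH2X4][Br,I]"),
        ("quinone", "O=C1C=CC(=O)C=C1"),
        ("rhodanine", "S1C(=S)NC(=O)C1"),
        ("catechol", "c1cc(O)c(O)cc1"),
        ("hydrazine", "[NX3H2][NX3H2]"),
        ("ene_rhodanine_like", "S1C(=S)N(C(=O)C1=C)"),
    ],
)


@dataclass(frozen=True)
class Stage1Thresholds:
    max_aromatic_rings: int = 4
    max_rotatable_bonds: int = 10
    max_hbd: int = 3
    max_clogp: float = 5.0
    max_tpsa: float = 125.0


@dataclass(frozen=True)
class Stage2Thresholds:
    max_logd: float = 5.0
    max_psa: float = 100.0
    combine: str = "and"   # "and": remove when both exceeded; "or": either

    def __post_init__(self) -> None:
        if self.combine not in ("and", "or"):
            raise ValueError("combine must be 'and' or 'or'")


# Ionizable-group SMARTS for the labeled logD surrogate: groups charged at
# pH 7.4 lower the apparent partition relative to clogP.
_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_BASIC_AMINE = Chem.MolFromSmarts("[NX3;H2,H1,H0;!$(NC=O);!$(Na);!$(N[a])]")
_LOGD_PENALTY = 1.5


def compute_descriptors(
    record: CompoundRecord,
    *,
    strict_rotors: bool = True,
) -> DescriptorSet:
    """Compute the triage descriptors for one compound.

    ``strict_rotors`` uses the strict rotatable-bond definition (amide C–N
    bonds excluded); set False to count them.  Caller-supplied ``logd`` /
    ``psa`` values in ``record.extra`` override the built-in surrogate.
    """
    mol = record.mol
    if mol is None:
        raise DescriptorError(f"{record.id}: structure failed to sanitize")

    ri = mol.GetRingInfo()
    aromatic_rings = sum(
        1 for ring in ri.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    rotors = rdMolDescriptors.CalcNumRotatableBonds(
        mol,
        rdMolDescriptors.NumRotatableBondsOptions.Strict
        if strict_rotors
        else rdMolDescriptors.NumRotatableBondsOptions.NonStrict,
    )
    hbd = rdMolDescriptors.CalcNumHBD(mol)
    clogp = Crippen.MolLogP(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)

    extra = record.extra or {}
    if "logd" in extra and extra["logd"] is not None and extra["logd"] == extra["logd"]:
        logd = float(extra["logd"])
    else:
        n_ionizable = len(mol.GetSubstructMatches(_ACID)) + len(
            mol.GetSubstructMatches(_BASIC_AMINE)
        )
        logd = clogp - _LOGD_PENALTY * n_ionizable
    if "psa" in extra and extra["psa"] is not None and extra["psa"] == extra["psa"]:
        psa = float(extra["psa"])
    else:
        psa = tpsa

    return DescriptorSet(
        aromatic_rings=aromatic_rings,
        rotatable_bonds=rotors,
        hbd=hbd,
        clogp=clogp,
        tpsa=tpsa,
        logd=logd,
        psa=psa,
        heavy_atoms=mol.GetNumHeavyAtoms(),
    )


def stage1_filter(
    deck: list[CompoundRecord],
    alerts: list[AlertSet] | None = None,
    thresholds: Stage1Thresholds = Stage1Thresholds(),
    descriptors: dict[str, DescriptorSet] | None = None,
) -> list[FilterVerdict]:
    """Apply alert and property rules; one verdict per deck member.

    Every rule that fires is listed in the verdict's reasons (alert label or
    property rule id such as ``aromatic_rings>4``). A descriptor failure is
    reported as a failed verdict with reason ``descriptor_error``.
    """
    if alerts is None:
        alerts = [DEFAULT_ALERTS]
    t = thresholds
    verdicts: list[FilterVerdict] = []
    for rec in deck:
        reasons: list[str] = []
        try:
            d = (descriptors or {}).get(rec.id) or compute_descriptors(rec)
            mol = rec.mol
        except (DescriptorError, Exception):
            verdicts.append(FilterVerdict(rec.id, False, ("descriptor_error",)))
            continue
        for aset in alerts:
            reasons += [f"alert:{aset.name}:{label}" for label in aset.hits(mol)]
        if d.aromatic_rings > t.max_aromatic_rings:
            reasons.append(f"aromatic_rings>{t.max_aromatic_rings}")
        if d.rotatable_bonds > t.max_rotatable_bonds:
            reasons.append(f"rotatable_bonds>{t.max_rotatable_bonds}")
        if d.hbd > t.max_hbd:
            reasons.append(f"hbd>{t.max_hbd}")
        if d.clogp > t.max_clogp:
            reasons.append(f"clogp>{t.max_clogp:g}")
        if d.tpsa > t.max_tpsa:
            reasons.append(f"tpsa>{t.max_tpsa:g}")
        verdicts.append(FilterVerdict(rec.id, not reasons, tuple(reasons)))
    return verdicts


def stage2_filter(
    pool: list[CompoundRecord],
    thresholds: Stage2Thresholds = Stage2Thresholds(),
    descriptors: dict[str, DescriptorSet] | None = None,
) -> list[FilterVerdict]:
    """Post-pooling logD/PSA cut.

    Under the default AND semantics a compound is removed only when logD
    exceeds ``max_logd`` AND PSA exceeds ``max_psa``; under OR, when either
    bound is exceeded. A missing descriptor fails with ``missing_descriptor``.
    """
    t = thresholds
    verdicts: list[FilterVerdict] = []
    for rec in pool:
        try:
            d = (descriptors or {}).get(rec.id) or compute_descriptors(rec)
        except Exception:
            verdicts.append(FilterVerdict(rec.id, False, ("missing_descriptor",)))
            continue
        if d.logd is None or d.psa is None:
            verdicts.append(FilterVerdict(rec.id, False, ("missing_descriptor",)))
            continue
        logd_hit = d.logd > t.max_logd
        psa_hit = d.psa > t.max_psa
        removed = (logd_hit and psa_hit) if t.combine == "and" else (logd_hit or psa_hit)
        if removed:
            reasons = []
            if t.combine == "and" or logd_hit:
                reasons.append(f"logd>{t.max_logd:g}")
            if t.combine == "and" or psa_hit:
                reasons.append(f"psa>{t.max_psa:g}")
            verdicts.append(FilterVerdict(rec.id, False, tuple(reasons)))
        else:
            verdicts.append(FilterVerdict(rec.id, True))
    return verdicts
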