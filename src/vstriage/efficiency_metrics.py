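"""Compound-quality and screening metrics: LE, LLE, hit rate, Kp,uu.

Ligand efficiency (LE) converts potency into an approximate binding free
energy per heavy atom: LE = 2.303·R·T·pIC50 / HAC with 2.303·R·T =
1.364 kcal/mol at 298.15 K (the common rounded constant 1.37 gives the
same values at the 2-decimal reporting precision; the constant is
configurable). Lipophilic ligand efficiency LLE = pIC50 − logP rewards
potency not bought with lipophilicity. The unbound brain-to-plasma
partition coefficient Kp,uu is the ratio of free brain to free plasma
concentration, each computed as total concentration × unbound fraction.

Values are rounded half-up at the precisions these quantities are
conventionally reported at: LE 2 d.p., LLE 1 d.p., hit rate 1 d.p. (as
a percentage), Kp,uu 2 d.p.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formula_mass import _round_half_up

__all__ = [
    "EfficiencyRecord",
    "PKRecord",
    "LE_CONSTANT_KCAL",
    "ligand_efficiency",
    "lipophilic_ligand_efficiency",
    "hit_rate",
    "kpuu",
]

LE_CONSTANT_KCAL = 1.364   # 2.303 * R * T at 298.15 K, kcal/mol


@dataclass(frozen=True)
class EfficiencyRecord:
    compound_id: str
    pic50: float
    heavy_atoms: int
    logp: float
    le: float
    lle: float

    @classmethod
    def compute(cls, compound_id: str, pic50: float, heavy_atoms: int, logp: float,
                constant: float = LE_CONSTANT_KCAL) -> "EfficiencyRecord":
        return cls(
            compound_id=compound_id,
            pic50=pic50,
            heavy_atoms=heavy_atoms,
            logp=logp,
            le=ligand_efficiency(pic50, heavy_atoms, constant=constant),
            lle=lipophilic_ligand_efficiency(pic50, logp),
        )


@dataclass(frozen=True)
class PKRecord:
    compound_id: str
    total_brain: float
    total_plasma: float
    fu_brain: float
    fu_plasma: float
    kpuu: float

    @classmethod
    def compute(cls, compound_id: str, total_brain: float, fu_brain: float,
                total_plasma: float, fu_plasma: float) -> "PKRecord":
        return cls(
            compound_id=compound_id,
            total_brain=total_brain,
            total_plasma=total_plasma,
            fu_brain=fu_brain,
            fu_plasma=fu_plasma,
            kpuu=kpuu(total_brain, fu_brain, total_plasma, fu_plasma),
        )


def ligand_efficiency(
    pic50: float,
    heavy_atoms: int,
    constant: float = LE_CONSTANT_KCAL,
    decimals: int | None = 2,
) -> float:
    """LE = constant × pIC50 / heavy-atom count, kcal/mol per heavy atom."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    le = constant * pic50 / heavy_atoms
    return le if decimals is None else _round_half_up(le, decimals)


def lipophilic_ligand_efficiency(
    pic50: float, logp: float, decimals: int | None = 1
) -> float:
    """LLE = pIC50 − logP."""
    lle = pic50 - logp
    return lle if decimals is None else _round_half_up(lle, decimals)


def hit_rate(n_hits: int, n_screened: int, decimals: int | None = 1) -> float:
    """Percentage of screened compounds that are hits."""
    if n_screened < 1:
        raise ValueError("n_screened must be >= 1")
    if not 0 <= n_hits <= n_screened:
        raise ValueError("need 0 <= n_hits <= n_screened")
    rate = 100.0 * n_hits / n_screened
    return rate if decimals is None else _round_half_up(rate, decimals)


def kpuu(
    total_brain: float,
    fu_brain: float,
    total_plasma: float,
    fu_plasma: float,
    decimals: int | None = 2,
) -> float:
    """Kp,uu = (total brain × fu,brain) / (total plasma × fu,plasma).

    Unit-free: any common concentration unit cancels. Unbound fractions
    must lie in (0, 1].
    """
    for name, v in [("total_brain", total_brain), ("total_plasma", total_plasma)]:
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    for name, v in [("fu_brain", fu_brain), ("fu_plasma", fu_plasma)]:
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    k = (total_brain * fu_brain) / (total_plasma * fu_plasma)
    return k if decimals is None else _round_half_up(k, decimals)
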