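"""Molecular-formula parsing and monoisotopic / average mass calculation.

High-resolution mass-spectrometry reports quote a "calcd" m/z for the
detected ion, obtained by summing atomic masses over the ion formula.
This module parses Hill-notation formula strings with an optional trailing
charge suffix (``C16H15N4OS+``, ``C13H11ClN3O2S2+``, ``SO4 2-``) and
computes

* the **monoisotopic mass**: sum of the masses of the most abundant
  isotope of each element, quoted to 4 decimal places as in HRMS reports;
* the **average mass**: sum of IUPAC standard atomic weights, quoted to
  1 decimal place as in low-resolution MS reports.

By default no electron-mass correction is applied for the charge: the
reported value is the plain atom-sum of the ion formula, which is the
convention the pinned regression anchors follow.  Setting
``electron_correct=True`` subtracts (adds) one electron mass
(~0.000549 u) per positive (negative) elementary charge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

__all__ = [
    "MolFormula",
    "FormulaParseError",
    "MassLookupError",
    "parse_formula",
    "render_formula",
    "monoisotopic_mass",
    "average_mass",
    "ELECTRON_MASS",
    "MASS_TABLE_VERSION",
]

# Constant table version: CODATA-2018 electron mass; monoisotopic masses from
# the AME2020 atomic mass evaluation; standard atomic weights from the IUPAC
# 2021 abridged table. Tests compare at 4 decimals, insulating against
# fifth-decimal revisions.
MASS_TABLE_VERSION = "2021-iupac/ame2020"

ELECTRON_MASS = 0.000548579909  # u

# element -> (monoisotopic mass of most abundant isotope, standard atomic weight)
_MASSES: dict[str, tuple[float, float]] = {
    "H": (1.0078250319, 1.008),
    "D": (2.0141017781, 2.014),
    "B": (11.0093054, 10.81),
    "C": (12.0, 12.011),
    "N": (14.0030740052, 14.007),
    "O": (15.9949146221, 15.999),
    "F": (18.9984031627, 18.998),
    "Na": (22.9897692820, 22.990),
    "Mg": (23.9850417, 24.305),
    "Si": (27.9769265350, 28.085),
    "P": (30.9737619984, 30.974),
    "S": (31.9720711744, 32.06),
    "Cl": (34.9688526932, 35.45),
    "K": (38.9637064864, 39.098),
    "Ca": (39.9625909, 40.078),
    "Fe": (55.9349363, 55.845),
    "Zn": (63.9291420, 65.38),
    "Se": (79.9165218, 78.971),
    "Br": (78.9183376, 79.904),
    "I": (126.9044719, 126.904),
    "Li": (7.0160034366, 6.94),
}


class FormulaParseError(ValueError):
    """Raised when a formula string cannot be parsed."""


class MassLookupError(KeyError):
    """Raised when an element has no entry in the mass table."""


@dataclass(frozen=True)
class MolFormula:
    """An elemental composition with an optional net charge.

    ``counts`` maps element symbols to strictly positive atom counts;
    ``charge`` is the net charge in elementary units (|charge| <= 10).
    """

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if not re.fullmatch(r"[A-Z][a-z]?", sym):
                raise FormulaParseError(f"invalid element symbol {sym!r}")
            if n <= 0:
                raise FormulaParseError(f"non-positive count for {sym!r}: {n}")
        if abs(self.charge) > 10:
            raise FormulaParseError(f"charge magnitude > 10: {self.charge}")

    def merged(self, other: "MolFormula") -> "MolFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return MolFormula(counts, self.charge + other.charge)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
# Charge suffix: "+", "-", "+2", or space-separated "2+"; unicode minus accepted.
# Digits immediately after an element symbol always bind as atom counts, so
# "C14H14N3O2S2+" is S2 with charge +1, while "SO4 2-" is sulfate.
_CHARGE = re.compile(r"(?:\s(\d+)([+\-−–])|([+\-−–])(\d*))$")


def parse_formula(text: str) -> MolFormula:
    """Parse a Hill-notation formula with an optional trailing charge.

    ``"C16H15N4OS+"`` -> counts {C:16, H:15, N:4, O:1, S:1}, charge +1.
    Unknown element symbols and malformed counts raise
    :class:`FormulaParseError` naming the offending token and position.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaParseError("empty formula string")
    body = text.strip()

    charge = 0
    m = _CHARGE.search(body)
    if m:
        mult = m.group(1) if m.group(2) else m.group(4)
        sign_ch = m.group(2) or m.group(3)
        sign = 1 if sign_ch == "+" else -1
        charge = sign * (int(mult) if mult else 1)
        body = body[: m.start()]
    if not body:
        raise FormulaParseError(f"no element tokens in {text!r}")

    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN.match(body, pos)
        if not m or m.start() != pos:
            raise FormulaParseError(
                f"malformed token at position {pos} in {text!r}: {body[pos:pos+3]!r}"
            )
        sym, digits = m.group(1), m.group(2)
        if sym not in _MASSES:
            raise FormulaParseError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaParseError(
                f"malformed count for {sym!r} at position {pos} in {text!r}"
            )
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolFormula(counts, charge)


def render_formula(f: MolFormula) -> str:
    """Render in Hill order (C, H, then alphabetical) with charge suffix."""
    syms = sorted(f.counts)
    ordered: list[str] = []
    if "C" in f.counts:
        ordered.append("C")
        syms.remove("C")
        if "H" in f.counts:
            ordered.append("H")
            syms.remove("H")
    ordered.extend(syms)
    body = "".join(s + (str(f.counts[s]) if f.counts[s] > 1 else "") for s in ordered)
    if f.charge:
        # sign-first for multiple charges ("+2"), so digits never read as counts
        mag = abs(f.charge)
        body += ("+" if f.charge > 0 else "-") + ("" if mag == 1 else str(mag))
    return body


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _mass(f: MolFormula, which: int, electron_correct: bool) -> float:
    total = 0.0
    for sym, n in f.counts.items():
        try:
            total += n * _MASSES[sym][which]
        except KeyError:
            raise MassLookupError(f"element {sym!r} missing from mass table") from None
    if electron_correct:
        total -= f.charge * ELECTRON_MASS
    return total


def monoisotopic_mass(
    f: MolFormula | str,
    *,
    electron_correct: bool = False,
    decimals: int | None = 4,
) -> float:
    """Monoisotopic mass in u, rounded half-up to ``decimals`` (default 4).

    ``decimals=None`` returns the unrounded sum.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    total = _mass(f, 0, electron_correct)
    return total if decimals is None else _round_half_up(total, decimals)


def average_mass(
    f: MolFormula | str,
    *,
    electron_correct: bool = False,
    decimals: int | None = 1,
) -> float:
    """Average (standard-atomic-weight) mass in u, rounded half-up (default 1 d.p.)."""
    if isinstance(f, str):
        f = parse_formula(f)
    total = _mass(f, 1, electron_correct)
    return total if decimals is None else _round_half_up(total, decimals)
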