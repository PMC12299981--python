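"""Elemental-formula and adduct-ion arithmetic for metabolite identification.

Monoisotopic masses, sodiated/protonated ion m/z with electron-mass
correction, metabolic mass shifts (O-demethylation, hydroxylation, neutral
losses of water and methanol), and ppm mass-error computation.

All internal arithmetic is carried at full floating precision; rounding is
applied only at display time (half-up, 4 decimals for m/z, 1 for ppm),
matching the convention of high-resolution QTOF work.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "AdductSpec",
    "ADDUCTS",
    "MassShift",
    "SHIFTS",
    "monoisotopic_mass",
    "adduct_mz",
    "apply_shift",
    "ppm_error",
    "round_half_up",
    "format_mz",
    "format_ppm",
]

# Monoisotopic atomic masses (Da). Frozen constants; the supported element
# set is deliberately small (macrolide CHNO chemistry plus alkali adducts).
ATOMIC_MASS: Dict[str, float] = {
    "C": 12.0000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "K": 38.9637069,
    "S": 31.97207069,
}

#: Electron rest mass (Da); subtracted once per positive charge.
ELECTRON_MASS = 0.00054858

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count composition, e.g. sirolimus C51H79NO13.

    Counts are non-negative integers; unsupported element symbols are
    rejected at construction.  Addition and subtraction are element-wise;
    subtraction below zero raises.
    """

    composition: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for el, n in self.composition.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"element count must be a non-negative int: {el}={n!r}")
            if n:
                clean[el] = n
        object.__setattr__(self, "composition", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``C51H79NO13``."""
        if not text:
            return cls({})
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.composition)
        for el, n in other.composition.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.composition)
        for el, n in other.composition.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(f"subtraction yields negative count for {el}")
            counts[el] = new
        return ElementalFormula(counts)

    def __str__(self) -> str:
        order = ["C", "H", "N", "O", "Na", "K", "S"]
        parts = []
        for el in order:
            n = self.composition.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts) or "(empty)"


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Neutral monoisotopic mass in Da (sum of count x atomic mass)."""
    return sum(n * ATOMIC_MASS[el] for el, n in formula.composition.items())


@dataclass(frozen=True)
class AdductSpec:
    """A cationic adduct: analyte plus an attached cation of given formula."""

    name: str
    added_formula: ElementalFormula
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("adduct charge must be a positive integer")


#: Built-in singly charged positive-mode adducts.
ADDUCTS: Dict[str, AdductSpec] = {
    "M+H": AdductSpec("M+H", ElementalFormula({"H": 1})),
    "M+Na": AdductSpec("M+Na", ElementalFormula({"Na": 1})),
    "M+K": AdductSpec("M+K", ElementalFormula({"K": 1})),
    "M+NH4": AdductSpec("M+NH4", ElementalFormula({"N": 1, "H": 4})),
}
# accept bracketed spellings like "[M+Na]+"
for _k in list(ADDUCTS):
    ADDUCTS[f"[{_k}]+"] = ADDUCTS[_k]


def adduct_mz(formula: ElementalFormula, adduct: AdductSpec) -> float:
    """m/z of the adduct ion, with electron-mass correction per charge.

    (mass(M + added) - z * m_e) / z.  For [M+Na]+ of C51H79NO13 this gives
    936.5444 at 4 dp; omitting the electron correction would give 936.5449.
    """
    if adduct.charge < 1:
        raise ValueError("charge must be >= 1")
    total = monoisotopic_mass(formula + adduct.added_formula)
    return (total - adduct.charge * ELECTRON_MASS) / adduct.charge


@dataclass(frozen=True)
class MassShift:
    """A signed metabolic/fragmentation mass shift derived from a formula change."""

    label: str
    delta: float

    def __neg__(self) -> "MassShift":
        return MassShift(f"-({self.label})", -self.delta)


def _loss(formula: str) -> float:
    return -monoisotopic_mass(ElementalFormula.parse(formula))


def _gain(formula: str) -> float:
    return monoisotopic_mass(ElementalFormula.parse(formula))


#: Canonical shifts: net -CH2 (O-demethylation), +O (hydroxylation),
#: -H2O and -CH3OH neutral losses, and the identity shift.
SHIFTS: Dict[str, MassShift] = {
    "demethylation": MassShift("demethylation", _loss("CH2")),
    "hydroxylation": MassShift("hydroxylation", _gain("O")),
    "water_loss": MassShift("water_loss", _loss("H2O")),
    "methanol_loss": MassShift("methanol_loss", _loss("CH4O")),
    "none": MassShift("none", 0.0),
}


def apply_shift(mz: float, shifts: Iterable[MassShift]) -> float:
    """Apply a list of mass shifts to an m/z; order-independent (pure sum)."""
    out = mz + sum(s.delta for s in shifts)
    if out <= 0:
        raise ValueError(f"shift composition yields non-positive m/z: {out}")
    return out


def ppm_error(measured: float, theoretical: float) -> float:
    """|measured - theoretical| / theoretical * 1e6 (theoretical denominator)."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return abs(measured - theoretical) / theoretical * 1e6


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (the convention used for printed m/z values)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_mz(mz: float) -> str:
    """Display form of an m/z: half-up to 4 decimals."""
    return f"{round_half_up(mz, 4):.4f}"


def format_ppm(ppm: float) -> str:
    """Display form of a ppm error: half-up to 1 decimal."""
    return f"{round_half_up(ppm, 1):.1f}"
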