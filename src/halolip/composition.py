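"""Elemental compositions, monoisotopic masses and adduct m/z arithmetic.

All formula bookkeeping in the package goes through
:class:`ElementComposition`; masses are computed from the IUPAC/CODATA
monoisotopic table below, restricted to the elements occurring in archaeal
lipids and their adducts.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from typing import Iterator

# Monoisotopic masses (Da) of the most abundant isotope, IUPAC 2021 values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

#: Mass of a proton (H minus one electron), Da.
PROTON_MASS = 1.007276
#: Mass of a hydrogen atom, Da (vendor-style charge carrier that neglects
#: the electron deficit of the cation).
HYDROGEN_MASS = 1.007825
ELECTRON_MASS = 0.00054857990907

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementComposition(Mapping):
    """Immutable element->count mapping with element-wise arithmetic.

    Counts are non-negative integers; subtraction that would drive any
    count negative raises ``ValueError`` (chemically impossible formula).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in MONOISOTOPIC_MASS:
                    raise KeyError(f"unknown element symbol: {el!r}")
                n = int(n)
                if n < 0:
                    raise ValueError(f"negative count for {el}: {n}")
                if n:
                    merged[el] = merged.get(el, 0) + n
        self._counts = dict(sorted(merged.items()))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        """Parse a Hill-style formula string such as ``'C43H88O3'``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def formula(self) -> str:
        """Hill notation: C first, H second, then alphabetical."""
        order = sorted(self._counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}"
            for el in order
        )

    # Mapping interface -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # Arithmetic ---------------------------------------------------------
    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) + n
        return ElementComposition(counts)

    def __sub__(self, other: "ElementComposition") -> "ElementComposition":
        counts = dict(self._counts)
        for el, n in other.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count "
                    f"({self.formula()} - {other.formula()})"
                )
        return ElementComposition(counts)

    def __mul__(self, k: int) -> "ElementComposition":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementComposition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementComposition({self.formula()!r})"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


WATER = ElementComposition(H=2, O=1)
H2 = ElementComposition(H=2)
SO3 = ElementComposition(S=1, O=3)
HEXOSE_RESIDUE = ElementComposition(C=6, H=10, O=5)  # anhydro-hexose C6H10O5
CH2 = ElementComposition(C=1, H=2)


def monoisotopic_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of an elemental composition.

    Empty composition has mass 0. Unknown element symbols raise ``KeyError``.
    """
    total = 0.0
    for el, n in comp.items():
        total += MONOISOTOPIC_MASS[el] * n
    return total


#: Adduct charge-carrier deltas, Da, under the physically exact "proton"
#: convention. The "hydrogen_atom" convention replaces the proton mass with
#: the H-atom mass (vendor software often neglects the electron).
_ADDUCT_PROTON: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
    "[M+NH4]+": monoisotopic_mass({"N": 1, "H": 4}) - ELECTRON_MASS,
    "[M+Na]+": MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS,
}
_ADDUCT_HATOM: dict[str, float] = {
    "[M+H]+": HYDROGEN_MASS,
    "[M+NH4]+": monoisotopic_mass({"N": 1, "H": 4}),
    "[M+Na]+": MONOISOTOPIC_MASS["Na"],
}

ADDUCTS = tuple(_ADDUCT_PROTON)


def adduct_delta(adduct: str, convention: str = "proton") -> float:
    """Charge-carrier mass added to the neutral monoisotopic mass."""
    table = {"proton": _ADDUCT_PROTON, "hydrogen_atom": _ADDUCT_HATOM}
    try:
        by_adduct = table[convention]
    except KeyError:
        raise ValueError(f"unknown convention: {convention!r}") from None
    try:
        return by_adduct[adduct]
    except KeyError:
        raise ValueError(f"unsupported adduct: {adduct!r}") from None


def adduct_mz(neutral_mass: float, adduct: str, convention: str = "proton") -> float:
    """m/z of a singly charged adduct ion of a neutral of given mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + adduct_delta(adduct, convention)
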