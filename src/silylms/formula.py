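"""Elemental formulas and exact-mass arithmetic.

A :class:`Formula` is an immutable map from element symbol to a
non-negative atom count — the unit of all mass arithmetic in this
package.  Atomic monoisotopic masses (mass of the most abundant
isotope) are hard-coded from the IUPAC atomic-mass evaluation rather
than computed from isotope distributions, so results are reproducible
with no external mass database.  Only monoisotopic and nominal
(integer) masses are supported; average molecular weights and isotope
patterns are out of scope.

Formulas are written and parsed in Hill notation: carbon first, then
hydrogen, then the remaining elements alphabetically (all elements
alphabetical when no carbon is present), e.g. ``C45H80O7Si5``.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

__all__ = [
    "ELEMENTS",
    "ELECTRON_MASS",
    "Formula",
    "FormulaError",
    "CompositionUnderflowError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "combine",
]

#: Monoisotopic masses in Da (most abundant isotope), IUPAC/AME values.
#: Carbon is exactly 12 by definition of the dalton.
ELEMENTS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840316273,
    "Na": 22.9897692809,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370649,
}

#: Integer (nominal) masses: the monoisotopic mass rounded to nearest integer.
NOMINAL: dict[str, int] = {el: round(m) for el, m in ELEMENTS.items()}

#: Electron rest mass in Da (CODATA).
ELECTRON_MASS: float = 0.000548579909


class FormulaError(ValueError):
    """A formula string could not be parsed, or an element is unknown."""


class CompositionUnderflowError(ValueError):
    """An arithmetic operation would drive an element count below zero."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """Immutable elemental composition: element symbol -> atom count.

    Zero-count entries are dropped, so ``Formula({"C": 1, "N": 0})``
    equals ``Formula({"C": 1})``.  Equality and hashing are
    element-wise on the stored counts.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for el, n in (counts or {}).items():
            if el not in ELEMENTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise FormulaError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise CompositionUnderflowError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        self._counts = clean

    # Mapping interface -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def get(self, el: str, default: int = 0) -> int:
        return self._counts.get(el, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el: object) -> bool:
        return el in self._counts

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # Arithmetic ---------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        return combine(self, other, 1)

    def __sub__(self, other: "Formula") -> "Formula":
        return combine(self, other, -1)

    def __mul__(self, k: int) -> "Formula":
        if k < 0:
            raise CompositionUnderflowError("cannot negate a composition")
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self._counts)

    # Masses -------------------------------------------------------------
    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def nominal_mass(self) -> int:
        return nominal_mass(self)

    # Formatting ---------------------------------------------------------
    def hill(self) -> str:
        return format_formula(self)

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:
        return f"Formula({format_formula(self)!r})"


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C45H80O7Si5"``.

    Each element symbol (capital letter, optional lowercase letter) may
    be followed by a positive integer count; a missing count means 1.
    Repeated symbols accumulate.  Raises :class:`FormulaError` naming
    the offending token on malformed input, zero counts, or unknown
    elements.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:pos + 3]!r}"
            )
        sym, digits = m.groups()
        if sym not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        if digits:
            n = int(digits)
            if n == 0:
                raise FormulaError(f"zero count for {sym} in {text!r}")
        else:
            n = 1
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return Formula(counts)


def format_formula(f: Mapping[str, int]) -> str:
    """Format a composition in Hill notation (C, H, then alphabetical)."""
    counts = {el: n for el, n in f.items() if n}
    if not counts:
        return ""
    order: list[str] = []
    if "C" in counts:
        order.append("C")
        if "H" in counts:
            order.append("H")
        order.extend(sorted(el for el in counts if el not in ("C", "H")))
    else:
        order.extend(sorted(counts))
    return "".join(el + (str(counts[el]) if counts[el] != 1 else "") for el in order)


def monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: sum of count x most-abundant-isotope mass."""
    try:
        return sum(n * ELEMENTS[el] for el, n in f.items())
    except KeyError as exc:  # pragma: no cover - Formula already validates
        raise FormulaError(f"unknown element symbol {exc.args[0]!r}") from None


def nominal_mass(f: Mapping[str, int]) -> int:
    """Nominal (integer) mass in Da: sum of count x integer isotope mass."""
    try:
        return sum(n * NOMINAL[el] for el, n in f.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element symbol {exc.args[0]!r}") from None


def combine(a: Mapping[str, int], b: Mapping[str, int], multiplier: int = 1) -> Formula:
    """Element-wise ``a + multiplier * b``.

    The multiplier may be negative only if every resulting count stays
    non-negative; otherwise :class:`CompositionUnderflowError` is
    raised (e.g. removing a t-butyl group from a species that has no
    nine hydrogens to give).
    """
    counts: dict[str, int] = dict(a.items() if isinstance(a, Formula) else a)
    for el, n in b.items():
        new = counts.get(el, 0) + multiplier * n
        if new < 0:
            raise CompositionUnderflowError(
                f"count of {el} would become {new} in {format_formula(a)} "
                f"+ {multiplier} x {format_formula(b)}"
            )
        counts[el] = new
    return Formula(counts)
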