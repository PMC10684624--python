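"""Adduct calculus: neutral formulas -> observed m/z, and mass errors.

Electrospray ionization (ESI) produces quasi-molecular ions by proton
gain or loss ([M+H]+, [M-H]-), sodium attachment ([M+Na]+), and
sodiated dimers ([2M+Na]+); electron ionization (EI) produces the
radical cation [M]+. .  Each of these is an :class:`AdductRule`:
a multimer count, a signed element delta, and a signed unit charge.

m/z is computed as (multimer x M + mass(delta) - charge x m_e) / |z|,
with the electron-mass term applied only when ``electron_correction``
is on (the default; physically correct for singly charged ions, a
0.55 mDa effect).  Only |z| = 1 is supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .formula import (
    ELECTRON_MASS,
    ELEMENTS,
    NOMINAL,
    CompositionUnderflowError,
    Formula,
    combine,
)

__all__ = [
    "AdductRule",
    "MassError",
    "ADDUCTS",
    "get_adduct",
    "mz",
    "nominal_mz",
    "ion_composition",
    "neutral_from_ion",
    "mass_error",
]


@dataclass(frozen=True)
class AdductRule:
    """How a neutral M becomes an observed ion.

    ``delta`` maps element symbol to a signed count gained (positive)
    or lost (negative) relative to ``multimer`` copies of the neutral;
    ``charge`` is the signed unit charge and must match the polarity.
    """

    name: str
    multimer: int
    delta: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        if self.multimer < 1:
            raise ValueError("multimer must be >= 1")
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")
        for el in self.delta:
            if el not in ELEMENTS:
                raise ValueError(f"unknown element in adduct delta: {el!r}")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def delta_mass(self) -> float:
        return sum(n * ELEMENTS[el] for el, n in self.delta.items())

    @property
    def delta_nominal(self) -> int:
        return sum(n * NOMINAL[el] for el, n in self.delta.items())


def _freeze(d: dict[str, int]) -> Mapping[str, int]:
    # dataclass(frozen) does not deep-freeze; keep deltas as plain dicts
    # owned by the registry and never mutated.
    return d


#: The registered adduct rules, keyed by printed name.  The four ESI
#: rules and the EI radical-cation rule are always present.
ADDUCTS: dict[str, AdductRule] = {
    r.name: r
    for r in (
        AdductRule("[M+H]+", 1, _freeze({"H": 1}), +1),
        AdductRule("[M-H]-", 1, _freeze({"H": -1}), -1),
        AdductRule("[M+Na]+", 1, _freeze({"Na": 1}), +1),
        AdductRule("[2M+Na]+", 2, _freeze({"Na": 1}), +1),
        AdductRule("[M]+.", 1, _freeze({}), +1),
    )
}


def get_adduct(name: str) -> AdductRule:
    """Look up an adduct rule by name; tolerates the typographic minus."""
    key = name.replace("−", "-").replace("–", "-").strip()
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(
            f"unknown adduct {name!r}; registered: {', '.join(ADDUCTS)}"
        ) from None


def ion_composition(neutral: Formula, rule: AdductRule) -> Formula:
    """Elemental composition of the ion: multimer x neutral + delta.

    Raises :class:`CompositionUnderflowError` if the delta removes an
    atom the (multimerized) neutral does not have, e.g. deprotonating
    an H-free formula.
    """
    total = neutral * rule.multimer
    for el, n in rule.delta.items():
        total = combine(total, Formula({el: abs(n)}), 1 if n > 0 else -1)
    return total


def neutral_from_ion(ion: Formula, rule: AdductRule) -> Formula:
    """Invert :func:`ion_composition`: recover the neutral from an ion composition."""
    total = ion
    for el, n in rule.delta.items():
        total = combine(total, Formula({el: abs(n)}), -1 if n > 0 else 1)
    if rule.multimer > 1:
        counts = {}
        for el, n in total.items():
            if n % rule.multimer:
                raise CompositionUnderflowError(
                    f"{total} is not divisible by multimer {rule.multimer}"
                )
            counts[el] = n // rule.multimer
        total = Formula(counts)
    return total


def mz(neutral: Formula, rule: AdductRule, electron_correction: bool = True) -> float:
    """Theoretical m/z of ``neutral`` observed under ``rule``.

    With electron correction on, the electron mass is subtracted for a
    net positive ion and added for a net negative ion.
    """
    if not neutral:
        raise ValueError("neutral formula is empty")
    ion = ion_composition(neutral, rule)  # validates H availability etc.
    m = ion.monoisotopic_mass
    if electron_correction:
        m -= rule.charge * ELECTRON_MASS
    return m / abs(rule.charge)


def nominal_mz(neutral: Formula, rule: AdductRule) -> int:
    """Unit-resolution (integer) m/z of ``neutral`` under ``rule``."""
    if not neutral:
        raise ValueError("neutral formula is empty")
    return ion_composition(neutral, rule).nominal_mass // abs(rule.charge)


@dataclass(frozen=True)
class MassError:
    """Observed-minus-theoretical mass error.

    ``absolute`` is in mDa, ``relative`` in ppm; both carry the sign of
    observed minus theoretical.
    """

    absolute: float  # mDa
    relative: float  # ppm

    def __abs__(self) -> float:
        return abs(self.absolute)


def mass_error(observed: float, theoretical: float) -> MassError:
    """Mass error of an observed m/z against a theoretical one."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    absolute = (observed - theoretical) * 1000.0
    relative = absolute / theoretical * 1000.0  # mDa/Da -> ppm
    return MassError(absolute=absolute, relative=relative)
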