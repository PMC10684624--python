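"""Candidate molecular-formula enumeration from accurate mass.

Given an observed m/z, an assumed adduct, per-element count bounds and
a tolerance, enumerate every elemental composition whose theoretical
ion m/z falls inside the tolerance window.  The search is a recursive
descent over elements in decreasing-mass order with residual-mass
interval pruning, which is exhaustive within the bounds and fast at
small-molecule scale.

Ring-plus-double-bond equivalents (RDBE) are available as an optional
plausibility filter, computed with tetravalent C and Si, trivalent N,
and monovalent H/F/Na:  rdbe = 1 + C + Si + N/2 - (H + F + Na)/2.
It is off by default: loose vendor searches routinely report
RDBE-implausible candidates, and reproducing such lists requires
keeping them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .formula import ELEMENTS, Formula, format_formula
from .ions import AdductRule, MassError, ion_composition, mass_error, mz

__all__ = [
    "DEFAULT_BOUNDS",
    "EnumerationSpec",
    "Candidate",
    "CandidateSet",
    "ConfigurationError",
    "CandidateOverflowError",
    "rdbe",
    "enumerate_formulas",
]

#: Default element bounds: generous enough to cover typical silylated
#: natural products (up to ~6 silyl groups) with slack.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 60),
    "H": (0, 100),
    "O": (0, 20),
    "Si": (0, 6),
    "N": (0, 5),
}

_RDBE_WEIGHT = {"C": 1.0, "Si": 1.0, "N": 0.5, "H": -0.5, "F": -0.5, "Na": -0.5}


class ConfigurationError(ValueError):
    """The enumeration request itself is invalid (e.g. empty bounds)."""


class CandidateOverflowError(RuntimeError):
    """More candidates than the configured cap; results are never truncated."""


def rdbe(f: Formula) -> float:
    """Ring-plus-double-bond equivalents of a composition."""
    return 1.0 + sum(_RDBE_WEIGHT.get(el, 0.0) * n for el, n in f.items())


@dataclass(frozen=True)
class EnumerationSpec:
    """What to enumerate: target m/z, tolerance, adduct and bounds.

    ``adduct=None`` means ``target_mz`` is a neutral monoisotopic mass
    rather than an observed ion m/z.  ``tolerance`` is in mDa.
    """

    target_mz: float
    tolerance: float = 10.0
    adduct: AdductRule | None = None
    element_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    rdbe_range: tuple[float, float] | None = None
    require_integer_rdbe: bool = False
    max_candidates: int = 100_000

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0 mDa")
        if not self.element_bounds:
            raise ConfigurationError("element bounds are empty")
        for el, (lo, hi) in self.element_bounds.items():
            if el not in ELEMENTS:
                raise ConfigurationError(f"unknown element in bounds: {el!r}")
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"invalid bounds for {el}: ({lo}, {hi})")


@dataclass(frozen=True)
class Candidate:
    """One enumerated composition: the ion form, its neutral, and the error."""

    formula: Formula  # ion composition (== neutral when adduct is None)
    neutral: Formula
    theoretical_mz: float
    error: MassError
    rdbe: float


@dataclass(frozen=True)
class CandidateSet:
    """Enumeration result, sorted by |absolute error| (ties by Hill string)."""

    target: EnumerationSpec
    candidates: tuple[Candidate, ...]

    @property
    def formulas(self) -> tuple[Formula, ...]:
        return tuple(c.formula for c in self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __contains__(self, f: object) -> bool:
        return any(c.formula == f for c in self.candidates)


def _neutral_window(spec: EnumerationSpec) -> tuple[float, float]:
    """Invert the adduct rule to a [lo, hi] window on the neutral mass."""
    tol_da = spec.tolerance / 1000.0
    if spec.adduct is None:
        return spec.target_mz - tol_da, spec.target_mz + tol_da
    r = spec.adduct
    # mz = (k*M + delta_mass - charge*m_e) / |z|  =>  solve for M
    from .formula import ELECTRON_MASS

    ion_mass = spec.target_mz * abs(r.charge) + r.charge * ELECTRON_MASS
    m = (ion_mass - r.delta_mass) / r.multimer
    return m - tol_da / r.multimer, m + tol_da / r.multimer


def enumerate_formulas(spec: EnumerationSpec) -> CandidateSet:
    """Exhaustively enumerate compositions matching ``spec``.

    Returns every composition — and only those — within the element
    bounds whose ion m/z lies within ``tolerance`` mDa of
    ``target_mz``, in deterministic order.  Raises
    :class:`CandidateOverflowError` if the candidate count would
    exceed ``max_candidates``.
    """
    lo, hi = _neutral_window(spec)
    # decreasing-mass order, so the light elements (with the finest mass
    # granularity) are assigned last where the window pins them down
    order = sorted(spec.element_bounds, key=lambda el: -ELEMENTS[el])
    bounds = [spec.element_bounds[el] for el in order]
    masses = [ELEMENTS[el] for el in order]
    # max mass attainable from elements i.. (for residual pruning)
    max_rest = [0.0] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        max_rest[i] = max_rest[i + 1] + bounds[i][1] * masses[i]

    found: list[Formula] = []
    counts = [0] * len(order)

    def descend(i: int, remaining_lo: float, remaining_hi: float) -> None:
        if remaining_hi < -1e-12:
            return
        if i == len(order):
            if remaining_lo <= 1e-12:  # 0 mass fits in [remaining_lo, remaining_hi]
                if len(found) >= spec.max_candidates:
                    raise CandidateOverflowError(
                        f"more than {spec.max_candidates} candidates; "
                        "tighten the tolerance or bounds"
                    )
                found.append(Formula(dict(zip(order, counts))))
            return
        cmin, cmax = bounds[i]
        m = masses[i]
        # counts below this cannot reach remaining_lo even with all the rest
        need = remaining_lo - max_rest[i + 1]
        c_from = max(cmin, math.ceil((need - 1e-12) / m)) if need > 0 else cmin
        c_to = min(cmax, math.floor((remaining_hi + 1e-12) / m))
        for c in range(c_from, c_to + 1):
            counts[i] = c
            descend(i + 1, remaining_lo - c * m, remaining_hi - c * m)
        counts[i] = 0

    descend(0, lo, hi)

    cands: list[Candidate] = []
    for neutral in found:
        if not neutral:
            continue
        if spec.adduct is None:
            ion = neutral
            theo = neutral.monoisotopic_mass
        else:
            try:
                ion = ion_composition(neutral, spec.adduct)
            except Exception:
                continue  # e.g. deprotonation of an H-free composition
            theo = mz(neutral, spec.adduct)
        err = mass_error(spec.target_mz, theo) if spec.target_mz > 0 else MassError(0, 0)
        if abs(err.absolute) > spec.tolerance + 1e-9:
            continue
        r = rdbe(ion)
        if spec.rdbe_range is not None and not (
            spec.rdbe_range[0] - 1e-9 <= r <= spec.rdbe_range[1] + 1e-9
        ):
            continue
        if spec.require_integer_rdbe and abs(r - round(r)) > 1e-9:
            continue
        cands.append(Candidate(ion, neutral, theo, err, r))

    cands.sort(key=lambda c: (abs(c.error.absolute), format_formula(c.formula)))
    return CandidateSet(target=spec, candidates=tuple(cands))
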