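"""Derivatization-series cross-check: narrow a parent formula.

Accurate mass alone rarely pins down a molecular formula — a 10 mDa
search window around one ion typically admits several elemental
compositions.  Derivatization adds an orthogonal constraint: if the
same compound is also observed carrying n silyl groups, the parent's
true formula F must have a partner F + n x site_delta among the
candidates for the derivatized ion, the partner must contain exactly
n silicon atoms (for an Si-free natural product), and F itself must
have enough oxygens and acidic protons to be silylated n times.
Intersecting candidate lists across the underivatized and derivatized
ions therefore eliminates most accidental mass matches.

Candidate sets may be enumerated internally (:mod:`.enumeration`) or
supplied externally, e.g. typed in from a vendor software report via
:func:`candidates_from_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .derivatization import DerivatizationReagent
from .enumeration import CandidateSet, ConfigurationError
from .formula import CompositionUnderflowError, Formula, combine, parse_formula
from .ions import ADDUCTS, AdductRule, neutral_from_ion

__all__ = [
    "ObservedIon",
    "CrosscheckResult",
    "crosscheck",
    "candidates_from_table",
]


@dataclass(frozen=True)
class ObservedIon:
    """One measured ion with a derivatization-degree hypothesis.

    ``candidates`` holds ion-form compositions, either enumerated from
    the m/z or supplied externally; ``candidate_errors`` optionally
    carries per-candidate |mass error| in mDa (used only for ranking
    ties among survivors).
    """

    mz: float | None
    adduct: AdductRule
    degree: int
    candidates: tuple[Formula, ...]
    candidate_errors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if not self.candidates:
            raise ValueError("candidate set is empty")

    @classmethod
    def from_candidate_set(cls, cs: CandidateSet, degree: int) -> "ObservedIon":
        if cs.target.adduct is None:
            raise ValueError("candidate set was enumerated without an adduct rule")
        return cls(
            mz=cs.target.target_mz,
            adduct=cs.target.adduct,
            degree=degree,
            candidates=cs.formulas,
            candidate_errors=tuple(abs(c.error.absolute) for c in cs.candidates),
        )


@dataclass(frozen=True)
class CrosscheckResult:
    """Survivors of the cross-check, with per-survivor evidence chains.

    ``surviving_parents`` are degree-0 candidates (in the stated
    ``form``, ion or neutral) ranked by summed |mass error| across the
    chain where errors are available, then by Hill string.  ``chains``
    maps each survivor to its matched candidate at every degree.
    ``eliminated`` maps each failed degree-0 candidate to the first
    violated rule: ``missing-pair@degree=n``, ``silicon-count``,
    ``oxygen-floor`` or ``hydrogen-floor``.
    """

    surviving_parents: tuple[Formula, ...]
    form: str  # "ion" | "neutral"
    chains: dict[Formula, dict[int, Formula]] = field(default_factory=dict)
    eliminated: dict[Formula, str] = field(default_factory=dict)


def crosscheck(
    ions: Sequence[ObservedIon],
    reagent: DerivatizationReagent,
    parent_si_free: bool = True,
    apply_site_constraint: bool = True,
) -> CrosscheckResult:
    """Intersect candidate sets across a derivatization series.

    A degree-0 candidate F survives iff

    a. for every ion of degree n > 0, F + n x site_delta (in matching
       ion form) is a member of that ion's candidate set;
    b. if ``parent_si_free``: F contains no Si and every degree-n
       partner contains exactly n Si;
    c. if ``apply_site_constraint``: the neutral parent has at least
       ``max(degrees)`` oxygens and at least as many hydrogens
       (the replaceable acidic protons must exist).

    Exactly one ion must have degree 0 and degrees must be unique.
    """
    degrees = [ion.degree for ion in ions]
    if degrees.count(0) != 1:
        raise ConfigurationError(
            f"exactly one degree-0 ion required, got {degrees.count(0)}"
        )
    if len(set(degrees)) != len(degrees):
        raise ConfigurationError(f"duplicate degrees in ion set: {sorted(degrees)}")

    base = next(ion for ion in ions if ion.degree == 0)
    deriv = sorted((ion for ion in ions if ion.degree > 0), key=lambda i: i.degree)
    max_degree = deriv[-1].degree if deriv else 0

    # Same proton-adduct family throughout -> work directly on ion
    # compositions (vendor tables print ion compositions); otherwise
    # reduce every candidate to its neutral first.
    same_family = all(ion.adduct.name == base.adduct.name for ion in ions)
    form = "ion" if same_family else "neutral"

    def as_working(f: Formula, ion: ObservedIon) -> Formula | None:
        if same_family:
            return f
        try:
            return neutral_from_ion(f, ion.adduct)
        except CompositionUnderflowError:
            return None

    deriv_sets: list[tuple[ObservedIon, set[Formula]]] = []
    for ion in deriv:
        ws = {w for f in ion.candidates if (w := as_working(f, ion)) is not None}
        deriv_sets.append((ion, ws))

    survivors: list[tuple[Formula, float]] = []
    chains: dict[Formula, dict[int, Formula]] = {}
    eliminated: dict[Formula, str] = {}

    for idx, cand in enumerate(base.candidates):
        work = as_working(cand, base)
        if work is None:
            eliminated[cand] = "adduct-reduction"
            continue
        # the neutral parent, for the floors (strip the adduct delta)
        try:
            neutral = neutral_from_ion(cand, base.adduct)
        except CompositionUnderflowError:
            eliminated[cand] = "adduct-reduction"
            continue

        if parent_si_free and neutral.get("Si", 0) != 0:
            eliminated[cand] = "silicon-count"
            continue
        if apply_site_constraint and max_degree > 0:
            if neutral.get("O", 0) < max_degree:
                eliminated[cand] = "oxygen-floor"
                continue
            if neutral.get("H", 0) < max_degree:
                eliminated[cand] = "hydrogen-floor"
                continue

        chain: dict[int, Formula] = {0: cand}
        err_sum = (
            base.candidate_errors[idx] if base.candidate_errors is not None else 0.0
        )
        reason = None
        for ion, ws in deriv_sets:
            expected = combine(work, reagent.site_delta, ion.degree)
            if expected not in ws:
                reason = f"missing-pair@degree={ion.degree}"
                break
            if parent_si_free and expected.get("Si", 0) != ion.degree * reagent.site_delta.get("Si", 0):
                reason = "silicon-count"
                break
            # record the matched candidate in its original (ion) form
            for j, f in enumerate(ion.candidates):
                if as_working(f, ion) == expected:
                    chain[ion.degree] = f
                    if ion.candidate_errors is not None:
                        err_sum += ion.candidate_errors[j]
                    break
        if reason is not None:
            eliminated[cand] = reason
            continue
        survivors.append((cand, err_sum))
        chains[cand] = chain

    survivors.sort(key=lambda t: (t[1], str(t[0])))
    return CrosscheckResult(
        surviving_parents=tuple(f for f, _ in survivors),
        form=form,
        chains=chains,
        eliminated=eliminated,
    )


def candidates_from_table(
    rows: Iterable[tuple[int, Sequence[str]]],
    adduct: AdductRule | None = None,
    mzs: dict[int, float] | None = None,
) -> list[ObservedIon]:
    """Build :class:`ObservedIon` records from printed candidate lists.

    Each row is ``(degree, [formula strings])`` as printed by vendor
    software; the strings are ion compositions and are trusted as-is
    (no m/z re-verification).  ``adduct`` defaults to [M+H]+, the form
    such tables usually print.
    """
    adduct = adduct or ADDUCTS["[M+H]+"]
    rows = list(rows)
    if not rows:
        raise ValueError("no rows supplied")
    ions: list[ObservedIon] = []
    for i, (degree, strings) in enumerate(rows):
        if not strings:
            raise ValueError(f"row {i}: empty formula list")
        try:
            cands = tuple(parse_formula(s) for s in strings)
        except Exception as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        ions.append(
            ObservedIon(
                mz=(mzs or {}).get(degree),
                adduct=adduct,
                degree=degree,
                candidates=cands,
            )
        )
    return ions
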