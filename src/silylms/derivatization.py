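"""Silylation derivatization model.

A silylation reagent replaces the acidic proton of a hydroxyl (or
thiol/amine) group with a silyl group, so each derivatized site
changes the elemental composition by a fixed net delta: +C6H14Si for
TBDMS (installed by MTBSTFA, nominal +114 Da per site) and +C3H8Si
for TMS (BSTFA/TMCS chemistry, nominal +72).  A parent derivatized n
times is therefore parent + n x site_delta, and a derivatization
series appears in a spectrum as a ladder of peaks spaced by the
site-delta mass.

Because each observed degree n requires n replaceable acidic protons,
the highest observed degree bounds the number of hydroxyl groups (and
hence oxygen atoms) of the parent from below; that inference is
:func:`infer_site_constraint`.

Reagents ship as data (``data/reagents.yaml``), not code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import yaml

from .formula import CompositionUnderflowError, Formula, combine, parse_formula
from .ions import AdductRule, mz, nominal_mz

__all__ = [
    "DerivatizationReagent",
    "SiteConstraint",
    "REAGENTS",
    "get_reagent",
    "derivatized_formula",
    "predict_series",
    "infer_site_constraint",
]


@dataclass(frozen=True)
class DerivatizationReagent:
    """A silylation reagent as a per-site composition delta.

    ``ei_losses`` are the characteristic radical losses under electron
    ionization; ``reporter_ion_mz`` an optional diagnostic ion.
    """

    name: str
    site_delta: Formula
    target_groups: frozenset[str]
    ei_losses: tuple[tuple[str, Formula], ...]
    reporter_ion_mz: float | None = None

    def __post_init__(self) -> None:
        if self.site_delta.get("Si", 0) < 1:
            raise ValueError(f"{self.name}: silyl site_delta must contain Si")


def _load_registry() -> dict[str, DerivatizationReagent]:
    text = resources.files("silylms.data").joinpath("reagents.yaml").read_text()
    raw = yaml.safe_load(text)
    reg: dict[str, DerivatizationReagent] = {}
    for name, entry in raw.items():
        reg[name] = DerivatizationReagent(
            name=name,
            site_delta=parse_formula(entry["site_delta"]),
            target_groups=frozenset(entry.get("target_groups", ["hydroxyl"])),
            ei_losses=tuple(
                (label, parse_formula(f)) for label, f in entry.get("ei_losses", [])
            ),
            reporter_ion_mz=entry.get("reporter_ion_mz"),
        )
    return reg


#: Shipped reagents, keyed by name (TBDMS, TMS).
REAGENTS: dict[str, DerivatizationReagent] = _load_registry()


def get_reagent(name: str) -> DerivatizationReagent:
    try:
        return REAGENTS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown reagent {name!r}; registered: {', '.join(REAGENTS)}"
        ) from None


def derivatized_formula(
    parent: Formula, reagent: DerivatizationReagent, n: int
) -> Formula:
    """Composition of ``parent`` carrying ``n`` silyl groups.

    The parent must have at least ``n`` hydrogens — each derivatization
    replaces one acidic proton, which must exist.
    """
    if n < 0:
        raise ValueError(f"derivatization degree must be >= 0, got {n}")
    if parent.get("H", 0) < n:
        raise CompositionUnderflowError(
            f"{parent} has only {parent.get('H', 0)} H but degree {n} "
            "requires as many replaceable protons"
        )
    return combine(parent, reagent.site_delta, n)


def predict_series(
    parent: Formula,
    reagent: DerivatizationReagent,
    degrees: Iterable[int],
    rule: AdductRule,
    resolution: str = "accurate",
) -> list[tuple[int, float]]:
    """Predicted m/z ladder for a derivatization series.

    One ``(degree, m/z)`` entry per requested degree.  ``resolution``
    is ``"accurate"`` (monoisotopic, electron-corrected) or
    ``"nominal"`` (integer masses, unit resolution).
    """
    degrees = sorted(set(int(d) for d in degrees))
    if not degrees:
        raise ValueError("degrees is empty")
    if resolution not in ("accurate", "nominal"):
        raise ValueError(f"resolution must be accurate|nominal, got {resolution!r}")
    out: list[tuple[int, float]] = []
    for d in degrees:
        species = derivatized_formula(parent, reagent, d)
        if resolution == "nominal":
            out.append((d, float(nominal_mz(species, rule))))
        else:
            out.append((d, mz(species, rule)))
    return out


@dataclass(frozen=True)
class SiteConstraint:
    """Lower bounds on derivatizable sites implied by observed degrees."""

    min_sites: int
    implied_min_O: int


def infer_site_constraint(
    observed_degrees: set[int] | Iterable[int], reagent: DerivatizationReagent
) -> SiteConstraint:
    """Bound the parent's site count from the observed derivatization degrees.

    The parent must carry at least ``max(observed_degrees)`` target
    groups; for hydroxyl-targeting reagents each such group brings one
    oxygen atom, giving an oxygen floor.
    """
    degs = sorted(set(observed_degrees))
    if not degs:
        raise ValueError("observed_degrees is empty")
    if degs[0] < 0:
        raise ValueError("degrees must be non-negative")
    m = degs[-1]
    implied_o = m if "hydroxyl" in reagent.target_groups else 0
    return SiteConstraint(min_sites=m, implied_min_O=implied_o)
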