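"""Synthetic spectra with the statistical structure the analysis assumes.

No raw spectra are deposited for the study system, so every pipeline
stage is exercised against generated data instead: ESI peak lists
containing adducted species of one parent across derivatization
degrees 0..n with Gaussian m/z calibration error and lognormal
(multiplicative) intensity noise, and unit-resolution EI spectra with
the molecular radical cation, the characteristic silyl losses (-15,
-57 for TBDMS) and the m/z 73 silyl/column-bleed ion.

Gaussian calibration error and lognormal intensity noise are the
simplest standard models for accurate-mass instruments; real spectra
additionally contain isotope envelopes, detector saturation and
chemical noise that this generator deliberately omits.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .derivatization import DerivatizationReagent, derivatized_formula
from .formula import Formula
from .ions import ADDUCTS, AdductRule, mz
from .spectra import BACKGROUND_IONS, PeakList, predict_ei_fragments

__all__ = ["SimulationSpec", "simulate_esi", "simulate_ei", "true_ratio"]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and noise model for a simulated ESI acquisition.

    ``degree_weights`` maps derivatization degree to relative
    abundance (the generative efficiency ratio is
    weight[0] / sum of weights[>=1]); ``adduct_weights`` maps adduct
    name to relative response.  ``calibration_sigma`` is the Gaussian
    m/z error SD in mDa; ``intensity_cv`` the coefficient of variation
    of the multiplicative lognormal intensity noise.
    """

    parent: Formula
    reagent: DerivatizationReagent
    n_sites: int
    degree_weights: Mapping[int, float]
    adduct_weights: Mapping[str, float] = field(
        default_factory=lambda: {"[M+H]+": 1.0}
    )
    base_intensity: float = 1000.0
    calibration_sigma: float = 0.0  # mDa
    intensity_cv: float = 0.0
    n_background: int = 0
    include_known_background: bool = False
    n_scans: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if not self.degree_weights or sum(self.degree_weights.values()) <= 0:
            raise ValueError("degree_weights must sum to a positive value")
        for d, w in self.degree_weights.items():
            if d < 0 or d > self.n_sites:
                raise ValueError(f"degree {d} outside 0..n_sites={self.n_sites}")
            if w < 0:
                raise ValueError("weights must be non-negative")
        for name in self.adduct_weights:
            if name not in ADDUCTS:
                raise ValueError(f"unknown adduct {name!r}")
        if self.calibration_sigma < 0 or self.intensity_cv < 0:
            raise ValueError("sigma and cv must be >= 0")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be > 0")


def true_ratio(spec: SimulationSpec) -> float | None:
    """The generative underivatized:derivatized ratio implied by the weights."""
    under = spec.degree_weights.get(0, 0.0)
    deriv = sum(w for d, w in spec.degree_weights.items() if d >= 1)
    if deriv == 0:
        return None
    return under / deriv


def simulate_esi(spec: SimulationSpec) -> list[PeakList]:
    """Simulate one ESI peak list per scan.

    Each scan holds one peak per (degree, adduct) pair with positive
    weight at m/z = theoretical + Normal(0, sigma) and intensity =
    base x degree weight x adduct weight x lognormal noise with unit
    mean, plus ``n_background`` uniform-random background peaks over
    the occupied m/z range.
    """
    rng = np.random.default_rng(spec.seed)
    mode = "ESI-neg" if all(
        ADDUCTS[a].charge < 0 for a in spec.adduct_weights
    ) else "ESI-pos"
    species: list[tuple[float, float]] = []  # (theoretical mz, mean intensity)
    for d, wd in sorted(spec.degree_weights.items()):
        if wd <= 0:
            continue
        f = derivatized_formula(spec.parent, spec.reagent, d)
        for name, wa in spec.adduct_weights.items():
            if wa <= 0:
                continue
            species.append((mz(f, ADDUCTS[name]), spec.base_intensity * wd * wa))
    if not species:
        raise ValueError("no (degree, adduct) pair has positive weight")
    mz_lo = min(m for m, _ in species) - 50.0
    mz_hi = max(m for m, _ in species) + 50.0
    # lognormal with unit mean: exp(N(-s^2/2, s)), s^2 = ln(1 + cv^2)
    s = float(np.sqrt(np.log1p(spec.intensity_cv**2)))
    sigma_da = spec.calibration_sigma / 1000.0

    scans: list[PeakList] = []
    for _ in range(spec.n_scans):
        pairs: list[tuple[float, float]] = []
        for theo, inten in species:
            m = theo + (rng.normal(0.0, sigma_da) if sigma_da > 0 else 0.0)
            fac = float(np.exp(rng.normal(-0.5 * s * s, s))) if s > 0 else 1.0
            pairs.append((m, inten * fac))
        for _ in range(spec.n_background):
            pairs.append(
                (float(rng.uniform(mz_lo, mz_hi)),
                 float(rng.uniform(0.0, 0.05 * spec.base_intensity)))
            )
        if spec.include_known_background:
            for _, bmz in BACKGROUND_IONS:
                pairs.append((bmz, float(rng.uniform(0.0, 0.05 * spec.base_intensity))))
        scans.append(
            PeakList.from_pairs(
                pairs,
                mode=mode,
                resolution="accurate",
                metadata={"simulated": True, "seed": spec.seed},
            )
        )
    return scans


def simulate_ei(
    parent: Formula,
    reagent: DerivatizationReagent,
    degree: int,
    intensity_profile: Sequence[float] | None = None,
    jitter: float = 0.0,
    seed: int = 0,
    include_reporter: bool = True,
) -> PeakList:
    """Simulate a unit-resolution EI spectrum of one derivatized species.

    Peaks sit at the nominal molecular ion, the reagent's loss
    fragments, and (for silylated species) the m/z 73 silyl/column-
    bleed ion, each jittered by Normal(0, ``jitter``) Da.  The default
    intensity profile makes the t-butyl loss the base peak for TBDMS
    species, reflecting the greater stability of the t-butyl radical
    over methyl.
    """
    rng = np.random.default_rng(seed)
    species = derivatized_formula(parent, reagent, degree)
    frags = predict_ei_fragments(species, reagent, resolution="nominal")
    if degree > 0 and include_reporter and not any(
        abs(m - 73.0) < 1.0 for _, m in frags
    ):
        frags = frags + [("silyl/column-bleed 73", 73.0)]
    if intensity_profile is None:
        profile = []
        for label, _ in frags:
            if "[M]+." in label:
                profile.append(60.0)
            elif "t-butyl" in label:
                profile.append(100.0)
            elif "73" in label or "reporter" in label:
                profile.append(40.0)
            else:
                profile.append(20.0)
    else:
        if len(intensity_profile) != len(frags):
            raise ValueError(
                f"intensity_profile length {len(intensity_profile)} != "
                f"{len(frags)} predicted peaks"
            )
        profile = list(intensity_profile)
    pairs = []
    for (label, m), inten in zip(frags, profile):
        jm = m + (float(rng.normal(0.0, jitter)) if jitter > 0 else 0.0)
        pairs.append((jm, inten))
    return PeakList.from_pairs(
        pairs,
        mode="EI",
        resolution="unit",
        metadata={"simulated": True, "species": str(species), "seed": seed},
    )
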