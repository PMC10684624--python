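"""Peak lists, scan averaging, annotation, EI fragments, efficiency.

This module carries the measured side of the pipeline: centroided peak
lists read from CSV (``mz,intensity``) or NIST-style MSP, averaging of
replicate scans, matching of predicted m/z values to peaks within a
tolerance, electron-ionization fragment prediction for silylated
species (alpha-cleavage losses of the methyl and t-butyl radicals from
TBDMS, 15 and 57 Da nominal), and the semi-quantitative derivatization
efficiency statistic: the intensity ratio of underivatized to
derivatized species, and the batch/flow efficiency factor.

Peak intensities of centroided lists stand in for integrated peak
areas; the ratio statistic is invariant to overall intensity scale, so
this substitution does not bias it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .derivatization import DerivatizationReagent, derivatized_formula
from .formula import Formula
from .ions import AdductRule, MassError, mass_error, mz, nominal_mz

__all__ = [
    "PeakList",
    "PeakListError",
    "Annotation",
    "AnnotationReport",
    "EfficiencyReport",
    "EfficiencyFactor",
    "BACKGROUND_IONS",
    "read_peaklist",
    "write_peaklist",
    "average_spectra",
    "annotate",
    "predict_ei_fragments",
    "derivatization_ratio",
    "efficiency_factor",
    "round_2sf",
]

#: Recurrent background ions reported but never identified in
#: MTBSTFA-derivatized flavonoid runs, plus the m/z 73 silyl/column-bleed
#: ion.  Shipped as tentative labels only; never subtracted.
BACKGROUND_IONS: tuple[tuple[str, float], ...] = (
    ("unassigned background (tentative)", 191.00),
    ("unassigned background (tentative)", 207.10),
    ("unassigned background (tentative)", 281.10),
    ("TMS+/column bleed (tentative)", 73.10),
)


class PeakListError(ValueError):
    """Peak-list data violates the container invariants."""


@dataclass(frozen=True)
class PeakList:
    """A centroided spectrum: strictly increasing m/z, intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "ESI-pos"  # ESI-pos | ESI-neg | EI
    resolution: str = "accurate"  # accurate | unit
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", np.asarray(self.mz, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise PeakListError("mz and intensity must be 1-D arrays of equal length")
        bad = np.where(np.diff(self.mz) <= 0)[0]
        if bad.size:
            raise PeakListError(
                f"mz not strictly increasing at rows {(bad + 1).tolist()}"
            )
        neg = np.where(self.intensity < 0)[0]
        if neg.size:
            raise PeakListError(f"negative intensities at rows {neg.tolist()}")

    def __len__(self) -> int:
        return self.mz.size

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[float, float]], **kwargs
    ) -> "PeakList":
        """Build from (m/z, intensity) pairs, sorting and merging duplicates."""
        pairs = sorted(pairs)
        merged: list[list[float]] = []
        for m, i in pairs:
            if merged and merged[-1][0] == m:
                merged[-1][1] += i
            else:
                merged.append([m, i])
        mzs = np.array([m for m, _ in merged], dtype=float)
        ints = np.array([i for _, i in merged], dtype=float)
        return cls(mz=mzs, intensity=ints, **kwargs)


# ---------------------------------------------------------------------------
# I/O


def read_peaklist(path: str | Path, format: str | None = None, **kwargs) -> PeakList:
    """Read a peak list from CSV (``mz,intensity`` header) or MSP.

    Format is inferred from the extension when not given.  MSP files
    are read through matchms; if the file holds several blocks, the
    first is returned.
    """
    path = Path(path)
    fmt = format or ("msp" if path.suffix.lower() == ".msp" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
        if not {"mz", "intensity"}.issubset(df.columns):
            raise PeakListError(f"{path}: CSV must have 'mz,intensity' header")
        return PeakList(
            mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy(), **kwargs
        )
    if fmt == "msp":
        from matchms.importing import load_from_msp

        spectra = list(load_from_msp(str(path), metadata_harmonization=False))
        if not spectra:
            raise PeakListError(f"{path}: no spectra in MSP file")
        s = spectra[0]
        meta = dict(kwargs.pop("metadata", {}) or {})
        meta.update({k: v for k, v in s.metadata.items() if k != "num_peaks"})
        return PeakList(
            mz=s.peaks.mz, intensity=s.peaks.intensities, metadata=meta, **kwargs
        )
    raise ValueError(f"unknown peak-list format {fmt!r}")


def write_peaklist(p: PeakList, path: str | Path, format: str | None = None) -> None:
    """Write a peak list as CSV or MSP (inferred from extension)."""
    path = Path(path)
    fmt = format or ("msp" if path.suffix.lower() == ".msp" else "csv")
    if fmt == "csv":
        pd.DataFrame({"mz": p.mz, "intensity": p.intensity}).to_csv(path, index=False)
        return
    if fmt == "msp":
        from matchms import Spectrum
        from matchms.exporting import save_as_msp

        meta = {str(k): str(v) for k, v in p.metadata.items()}
        meta.setdefault("compound_name", meta.get("label", "spectrum"))
        s = Spectrum(
            mz=p.mz.astype(float),
            intensities=p.intensity.astype(float),
            metadata=meta,
            metadata_harmonization=False,
        )
        save_as_msp([s], str(path), mode="w")
        return
    raise ValueError(f"unknown peak-list format {fmt!r}")


# ---------------------------------------------------------------------------
# Averaging


def average_spectra(scans: Sequence[PeakList], bin_tolerance: float = 5.0) -> PeakList:
    """Average replicate scans into one spectrum.

    Peaks within ``bin_tolerance`` mDa across scans are merged into one
    peak with intensity-weighted mean m/z; the intensity is the mean
    over scans, a peak absent from a scan counting as zero.  This is
    the combination step used before computing relative abundances
    from replicate acquisitions.
    """
    if not scans:
        raise ValueError("no scans to average")
    modes = {s.mode for s in scans}
    if len(modes) > 1:
        raise ValueError(f"scans mix acquisition modes: {sorted(modes)}")
    tol_da = bin_tolerance / 1000.0
    allmz = np.concatenate([s.mz for s in scans])
    allint = np.concatenate([s.intensity for s in scans])
    order = np.argsort(allmz, kind="stable")
    allmz, allint = allmz[order], allint[order]
    # single-linkage clustering along the m/z axis
    out_mz: list[float] = []
    out_int: list[float] = []
    start = 0
    n = len(allmz)
    for i in range(1, n + 1):
        if i == n or allmz[i] - allmz[i - 1] > tol_da:
            seg_mz = allmz[start:i]
            seg_int = allint[start:i]
            w = seg_int.sum()
            center = float((seg_mz * seg_int).sum() / w) if w > 0 else float(seg_mz.mean())
            out_mz.append(center)
            out_int.append(float(seg_int.sum()) / len(scans))
            start = i
    first = scans[0]
    return PeakList(
        mz=np.array(out_mz),
        intensity=np.array(out_int),
        mode=first.mode,
        resolution=first.resolution,
        metadata={"n_scans_averaged": len(scans), **first.metadata},
    )


# ---------------------------------------------------------------------------
# Annotation


@dataclass(frozen=True)
class Annotation:
    """One prediction matched to one peak."""

    peak_index: int
    species_label: str
    predicted_mz: float
    error: MassError

    @property
    def observed_mz(self) -> float:
        return self.predicted_mz + self.error.absolute / 1000.0


@dataclass(frozen=True)
class AnnotationReport:
    """Matched annotations plus the predictions that found no peak."""

    annotations: tuple[Annotation, ...]
    unmatched: tuple[tuple[str, float], ...]

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)

    def to_frame(self, p: PeakList) -> pd.DataFrame:
        rows = [
            {
                "peak_mz": p.mz[a.peak_index],
                "intensity": p.intensity[a.peak_index],
                "label": a.species_label,
                "predicted_mz": a.predicted_mz,
                "error_mda": a.error.absolute,
            }
            for a in self.annotations
        ]
        return pd.DataFrame(
            rows, columns=["peak_mz", "intensity", "label", "predicted_mz", "error_mda"]
        )


def _default_tolerance_da(p: PeakList) -> float:
    return 0.5 if p.resolution == "unit" else 0.005


def annotate(
    p: PeakList,
    predictions: Sequence[tuple[str, float]],
    tolerance: float | None = None,
) -> AnnotationReport:
    """Match predicted (label, m/z) pairs to the nearest peaks.

    ``tolerance`` is in Da; it defaults to 0.5 Da for unit-resolution
    spectra and 5 mDa for accurate-mass spectra.  Each prediction
    matches at most one peak — the nearest within tolerance, the more
    intense peak winning an exact distance tie.  Predictions with no
    peak in range are reported as unmatched.
    """
    if not predictions:
        raise ValueError("predictions are empty")
    tol = _default_tolerance_da(p) if tolerance is None else float(tolerance)
    hits: list[Annotation] = []
    misses: list[tuple[str, float]] = []
    for label, pred in predictions:
        if len(p) == 0:
            misses.append((label, pred))
            continue
        j = int(np.searchsorted(p.mz, pred))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(p):
                d = abs(p.mz[k] - pred)
                if d <= tol + 1e-12:
                    key = (d, -p.intensity[k])  # tie -> more intense wins
                    if best is None or key < best[0]:
                        best = (key, k)
        if best is None:
            misses.append((label, pred))
        else:
            k = best[1]
            hits.append(
                Annotation(
                    peak_index=k,
                    species_label=label,
                    predicted_mz=pred,
                    error=mass_error(float(p.mz[k]), pred),
                )
            )
    return AnnotationReport(annotations=tuple(hits), unmatched=tuple(misses))


# ---------------------------------------------------------------------------
# EI fragment prediction

_GENERIC_LOSSES: tuple[tuple[str, Formula], ...] = (
    ("methyl", Formula({"C": 1, "H": 3})),
)


def predict_ei_fragments(
    species: Formula,
    reagent: DerivatizationReagent,
    resolution: str = "nominal",
) -> list[tuple[str, float]]:
    """Predict the EI spectrum skeleton of a (possibly silylated) species.

    Emits the molecular radical cation [M]+. and one [M - loss]+ peak
    per characteristic radical loss — the reagent's alpha-cleavage
    losses when the species carries silyl groups, a generic methyl
    loss otherwise — plus the reagent's reporter ion if it has one.
    A loss that is not subtractable from the composition is omitted
    with a warning.
    """
    from .ions import ADDUCTS

    ei = ADDUCTS["[M]+."]
    losses = reagent.ei_losses if species.get("Si", 0) > 0 else _GENERIC_LOSSES

    def ion_mz(f: Formula) -> float:
        return float(nominal_mz(f, ei)) if resolution == "nominal" else mz(f, ei)

    out: list[tuple[str, float]] = [(f"{species} [M]+.", ion_mz(species))]
    for label, loss in losses:
        try:
            frag = species - loss
        except Exception:
            warnings.warn(
                f"loss {label} ({loss}) not subtractable from {species}; skipped"
            )
            continue
        out.append((f"{species} [M-{loss}]+ (-{label})", ion_mz(frag)))
    if reagent.reporter_ion_mz is not None:
        rep = reagent.reporter_ion_mz
        out.append(
            (f"{reagent.name}+ reporter", round(rep) if resolution == "nominal" else rep)
        )
    return out


# ---------------------------------------------------------------------------
# Efficiency


@dataclass(frozen=True)
class EfficiencyReport:
    """Underivatized-to-derivatized intensity ratio for one sample.

    ``ratio`` is None when no derivatized signal was matched (the
    statistic is then undefined); ``complete_derivatization`` flags
    the opposite extreme, where no underivatized signal remains.
    """

    underivatized_intensity: float
    derivatized_intensity: float
    label: str = "other"  # batch | flow | other
    per_degree: dict[int, float] = field(default_factory=dict)

    @property
    def ratio(self) -> float | None:
        if self.derivatized_intensity == 0:
            return None
        return self.underivatized_intensity / self.derivatized_intensity

    @property
    def complete_derivatization(self) -> bool:
        return self.underivatized_intensity == 0 and self.derivatized_intensity > 0

    @property
    def no_derivatized_signal(self) -> bool:
        return self.derivatized_intensity == 0


def derivatization_ratio(
    p: PeakList,
    parent: Formula,
    reagent: DerivatizationReagent,
    adducts: Sequence[AdductRule],
    max_degree: int,
    tolerance: float | None = None,
    label: str = "other",
) -> EfficiencyReport:
    """Semi-quantitative derivatization efficiency from one spectrum.

    Predicts the quasi-molecular m/z of the parent at degrees
    0..max_degree under every listed adduct, matches them to the peak
    list, and returns summed matched intensity of the underivatized
    species over the summed intensity of all derivatized degrees.
    A lower ratio means more complete derivatization.
    """
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    if not adducts:
        raise ValueError("no adducts given")
    preds: list[tuple[str, float]] = []
    key: dict[str, int] = {}
    for d in range(0, max_degree + 1):
        species = derivatized_formula(parent, reagent, d)
        for rule in adducts:
            lbl = f"{parent}+{d}x{reagent.name} {rule.name}"
            preds.append((lbl, mz(species, rule)))
            key[lbl] = d
    report = annotate(p, preds, tolerance=tolerance)
    # one physical peak counts once per degree even if several
    # predictions land on it
    seen: dict[int, set[int]] = {}
    per_degree: dict[int, float] = {d: 0.0 for d in range(max_degree + 1)}
    for a in report.annotations:
        d = key[a.species_label]
        if a.peak_index in seen.setdefault(d, set()):
            continue
        seen[d].add(a.peak_index)
        per_degree[d] += float(p.intensity[a.peak_index])
    under = per_degree[0]
    deriv = sum(v for d, v in per_degree.items() if d >= 1)
    return EfficiencyReport(
        underivatized_intensity=under,
        derivatized_intensity=deriv,
        label=label,
        per_degree=per_degree,
    )


@dataclass(frozen=True)
class EfficiencyFactor:
    """Batch-over-flow efficiency gain."""

    raw: float
    rounded_2sf: float
    undefined: bool = False


def round_2sf(x: float) -> float:
    """Round to two significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + 1)


def efficiency_factor(batch: EfficiencyReport, flow: EfficiencyReport) -> EfficiencyFactor:
    """How many times more efficient the flow method is than batch.

    The factor is batch ratio over flow ratio (smaller ratio = more
    derivatized).  An undefined or zero flow ratio yields an explicit
    infinite/undefined flag rather than a number.
    """
    b, f = batch.ratio, flow.ratio
    if b is None:
        return EfficiencyFactor(raw=math.nan, rounded_2sf=math.nan, undefined=True)
    if f is None or f == 0:
        return EfficiencyFactor(raw=math.inf, rounded_2sf=math.inf, undefined=True)
    raw = b / f
    return EfficiencyFactor(raw=raw, rounded_2sf=round_2sf(raw))
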