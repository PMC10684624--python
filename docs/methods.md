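# Methods

## Mass model

All arithmetic is carried out on elemental compositions (maps from
element symbol to non-negative count). Monoisotopic masses use the
most-abundant-isotope masses from the IUPAC atomic-mass evaluation,
hard-coded to ≤1e-5 Da (C exactly 12), rather than derived from an
isotope-distribution library: the supported element set is small
(C, H, N, O, F, Na, Si, P, S, Cl, K) and a frozen table makes every
number reproducible with no external database. Nominal masses are the
monoisotopic masses rounded to integers. Average (molecular-weight)
masses and isotope fine structure are deliberately out of scope — the
workflows this package supports use only monoisotopic and nominal
values.

Ion m/z is `(k·M + Δm − z·mₑ)/|z|` for an adduct with multimer count
k, composition delta Δ and signed unit charge z. The electron-mass
correction (±0.549 mDa) is on by default; published "expected" values
for silylated species sometimes mix conventions, which is one reason
the package's accurate-mass comparisons use a ±2 mDa band rather than
chasing the fourth decimal. Only singly charged ions are modeled:
small silylated phenolics do not form multiply charged species under
ESI in practice. Mass errors are reported observed-minus-theoretical
in mDa and ppm. Note that "relative error" figures quoted alongside
some published assignments do not reproduce from
theoretical-minus-observed arithmetic under either electron
convention; this package always reports its own computed errors and
makes no attempt to force agreement with such figures.

## Derivatization model

A silylation reagent is a per-site net composition delta (silyl group
minus the replaced acidic proton): TBDMS = +C6H14Si (nominal +114),
TMS = +C3H8Si (+72), shipped as data in `data/reagents.yaml`. A parent
derivatized n times is `parent + n·Δ`, which requires n replaceable
protons in the parent. Degree assignments attached to observed ions
are treated as hypotheses about that ion, not claims about the overall
solution composition (under EI, members of a "series" may equally be
fragments of one highly derivatized species). Regioselectivity,
kinetics and steric accessibility are not modeled.

Because each site consumes one hydroxyl proton, the largest observed
degree bounds the hydroxyl count — and hence the oxygen count — of the
parent from below (`infer_site_constraint`).

EI fragment prediction emits the molecular radical cation plus one
peak per characteristic radical loss: the reagent's α-cleavage losses
(methyl 15, t-butyl 57 for TBDMS) when the species carries silicon, a
generic methyl loss otherwise (methyl loss is routine for methoxylated
natural products; it covers, e.g., an underivatized M 378 fragmenting
to 363). One published fragment list prints "8515" where the
accompanying text prints 815; the package treats this as a
typographical variant of 815.

## Formula enumeration

Candidates for an observed m/z are enumerated by first inverting the
adduct rule to a neutral-mass window, then recursively assigning
element counts in decreasing-mass order with residual-mass interval
pruning. The search is exhaustive within the element bounds (verified
in tests against a brute-force product-loop oracle) and deterministic:
candidates are sorted by |mass error|, ties by Hill string. Exceeding
the candidate cap raises an explicit error; results are never silently
truncated.

Defaults: bounds C 0–60, H 0–100, O 0–20, Si 0–6, N 0–5 (covering
typical silylated flavonoids with slack — enumerating heavily
silylated ions of H-rich parents may need a wider H bound); tolerance
10 mDa, which is deliberately loose: vendor formula searches that
produced published candidate lists were evidently run with several-mDa
slack, and a tight window would fail to reproduce their candidates.
RDBE filtering (1 + C + Si + N/2 − (H+F+Na)/2, Si tetravalent) is off
by default because such lists routinely contain RDBE-implausible rows
that a filter would remove; it is available as an opt-in.

## Series cross-check

Inputs are one ion per derivatization degree (exactly one degree-0
ion), each with a candidate list — enumerated internally or supplied
externally (printed vendor lists are accepted as-is, without m/z
re-verification). A degree-0 candidate survives iff:

1. pairing: for every degree n > 0, candidate + n·Δ is present in
   that ion's candidate list (exact element-wise arithmetic, not
   mass-window matching — deterministic and what the printed tables
   demonstrably do);
2. silicon rule (optional, default on): the parent is Si-free — a
   natural-product assumption, overridable — and each degree-n partner
   carries exactly n Si;
3. site floors (optional, default on): the neutral parent has at
   least max(degree) oxygens and max(degree) hydrogens. Floors are
   evaluated on the neutral obtained by stripping the adduct delta
   from ion-form candidates; each silylation must find an acidic
   proton to replace.

When all ions share one adduct family the check runs directly on ion
compositions (the form vendor tables print); mixed adducts are first
reduced to neutrals. Eliminations record the first violated rule
(rules are checked in the order: silicon count, oxygen floor, hydrogen
floor, pairing by increasing degree). If several parents survive, all
are reported, ranked by summed |mass error| over the chain when
per-candidate errors are known; the tool never auto-picks one.
Rule-based elimination is all the tool claims: whether a human analyst
additionally discards candidates on chemical intuition is outside its
scope.

## Peak lists, annotation, efficiency

Peak lists are centroided (strictly increasing m/z, non-negative
intensities), read/written as CSV (`mz,intensity`) or NIST-style MSP
(via matchms). Replicate-scan averaging merges peaks within a mDa
bin tolerance (single-linkage along the m/z axis) into
intensity-weighted mean m/z, with the mean intensity counting a peak
absent from a scan as zero — the combination step used before
computing relative abundances.

Annotation matches each predicted (label, m/z) to the nearest peak
within tolerance — 5 mDa default for accurate-mass spectra, 0.5 Da
for unit-resolution — with an exact-distance tie going to the more
intense peak. Unmatched predictions are reported, never dropped
silently. A short list of recurrent unassigned background ions
(191.00, 207.10, 281.10, and the m/z 73 silyl/column-bleed ion) ships
as tentative labels only and is never subtracted.

The derivatization-efficiency statistic is the summed matched
intensity of the degree-0 species over the summed matched intensity of
degrees 1..max, using peak intensities of centroided lists as a proxy
for integrated areas (raw profile data are typically not available,
and the ratio is invariant to overall intensity scale, so the proxy
does not bias it). Zero derivatized signal yields an explicit
undefined-ratio flag; zero underivatized signal a
complete-derivatization flag (ratio 0). The efficiency factor between
two preparations is the ratio of their ratios, reported raw and at two
significant figures.

## Synthetic data

The ESI generator emits, per scan, one peak per (degree, adduct) pair
with positive weight: m/z = theoretical + Normal(0, σ) with σ the
calibration error in mDa, intensity = base × degree weight × adduct
weight × a unit-mean lognormal with the requested coefficient of
variation, plus optional uniform-random background peaks. The EI
generator emits the nominal molecular ion, the reagent's loss
fragments and the m/z 73 silyl ion, with the t-butyl-loss peak as base
peak for TBDMS species (the more stable radical leaves more readily).
Both are fully reproducible from the seed.

These are explicit, deliberately simple noise models chosen in the
absence of any published noise characterization. The generator omits
isotope envelopes, chemical noise, detector saturation and
chromatography; passing parameter-recovery tests therefore shows the
pipeline's arithmetic and matching are sound under the stated noise
model, not that the defaults are calibrated to any particular
instrument. Default study-like conditions used in tests: degree
weights 0.366:1 (underivatized:4×, the flow-like composition) or
9.08:1 (batch-like), base intensity 1000, σ = 2 mDa and CV = 5% for
the noisy Monte-Carlo check (200 replicates, mean recovered ratio
within 3 SE of truth).

## Numerical and design notes

- Formula parsing/formatting uses Hill notation; parsing then
  formatting round-trips exactly (property-tested).
- Enumeration recursion tolerances use 1e-12 Da epsilons so boundary
  candidates are kept deterministically.
- The cross-check's parameter-recovery property (random Si-free
  parents with ≤6 sites, ideal ions at degrees {0,1,s}, 5 mDa
  enumeration) always retains the true parent; tests run it with an H
  bound of 160 so the bounds cover the heavily silylated ions.
- One published positive-mode assignment (m/z 417.2466 as a
  twice-derivatized species) is inconsistent with the series
  arithmetic (~110 mDa from any adduct of the once- or
  twice-derivatized composition) and is excluded from validation.
- Problem sizes throughout (candidate lists of ~10²–10³, 200-replicate
  Monte-Carlo) were chosen as the scale at which the deterministic
  checks are exact and the stochastic checks statistically sharp; the
  whole suite runs in well under a minute.

## Known limitations

- No isotope-pattern scoring: two compositions inside the same mass
  window are distinguished only by the derivatization cross-check.
- Only |z| = 1 adducts; no in-source fragmentation in ESI mode.
- The efficiency statistic assumes comparable ionization response
  across derivatization degrees, as semi-quantitative practice does;
  it is a relative, not absolute, measure.
- MSP support targets the simple NIST text dialect (one block per
  spectrum, `Num Peaks` + pairs).
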