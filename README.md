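# silylms

Mass-spectrometric interpretation of silylation derivatization series.

Silylation (e.g. with MTBSTFA, which installs tert-butyldimethylsilyl,
TBDMS, groups) replaces the acidic proton of each hydroxyl group with a
silyl group, making polar natural products such as flavonoids volatile
enough for GC analysis. In the mass spectra this leaves a strong
arithmetic signature: every derivatized site shifts the composition by a
fixed net delta (+C6H14Si for TBDMS, +114 Da nominal; +C3H8Si for TMS,
+72), so a compound observed at several derivatization degrees produces
a ladder of ions spaced by the site delta, and under electron ionization
each TBDMS site α-cleaves to lose a methyl (15 Da) or t-butyl (57 Da)
radical. `silylms` turns that signature into reusable desk calculations
for analysts interpreting GC–MS and ESI HR-MS data of derivatized small
molecules:

- **m/z prediction** for neutral formulas under the standard adduct
  rules `[M+H]+`, `[M-H]-`, `[M+Na]+`, `[2M+Na]+` and the EI radical
  cation `[M]+.`, at accurate (monoisotopic, electron-corrected) or
  unit (nominal) resolution, plus EI fragment prediction for silylated
  species.
- **Formula enumeration**: all elemental compositions within a mDa
  tolerance of an observed m/z, under element bounds, with an optional
  RDBE filter — exhaustive recursive search with residual-mass pruning.
- **Series cross-check**: intersect candidate-formula lists across
  derivatization degrees. A degree-0 candidate F survives only if
  F + n×C6H14Si appears among the degree-n candidates, the partner
  carries exactly n Si, and F has enough oxygens and acidic protons to
  be silylated n times. This typically collapses an ambiguous
  accurate-mass search to a single parent formula.
- **Derivatization efficiency**: the underivatized:derivatized
  intensity ratio from a peak list (lower = more complete reaction) and
  the efficiency factor between two preparations (e.g. flow vs batch).
- **Synthetic spectra**: seeded ESI/EI spectrum generators with
  Gaussian calibration error and lognormal intensity noise, so the
  whole pipeline is testable by parameter recovery without raw data.

## Worked example

Quercetin (C15H10O7, five hydroxyls) derivatized 2–5 times with TBDMS,
as seen by GC–EI-MS at unit resolution:

```sh
$ silylms series --parent C15H10O7 --reagent TBDMS --degrees 2:5 --adduct "[M]+." --nominal
degree,mz
2,530
3,644
4,758
5,872
```

The ladder is spaced by 114 (one TBDMS per step). The fully derivatized
species has monoisotopic mass

```sh
$ silylms mass C45H80O7Si5
formula,monoisotopic_da,nominal_da
C45H80O7Si5,872.4750,872
```

and its EI spectrum shows the α-cleavage fragments at 857 (−CH3) and
815 (−C4H9), the latter more intense because the t-butyl radical is the
more stable leaving group.

For an unknown flavonoid observed at m/z 379.1202 `[M+H]+` that
silylates once (493.2097) and four times (835.4821), enumerate
candidates and cross-check them across the series:

```sh
$ silylms enumerate --mz 493.2097 --adduct "[M+H]+" --tol-mda 5 --elements "C0-30,H0-60,O0-15,Si0-2"
formula,theoretical_mz,error_mda,error_ppm,rdbe
C21H37O11Si,493.2100,-0.26,-0.54,4.5
C24H37O7Si2,493.2072,2.47,5.00,8.5
...

$ silylms crosscheck --config ztf.yaml   # ions + candidate lists per degree
INFO silylms: eliminated C22H19O6: missing-pair@degree=4
INFO silylms: eliminated C29H15O: oxygen-floor
INFO silylms: eliminated C11H23O14: missing-pair@degree=4
INFO silylms: eliminated C18H19O9: missing-pair@degree=1
survivor_ion_formula,chain
C15H23O11,0:C15H23O11;1:C21H37O11Si;4:C39H79O11Si4
```

Only one parent candidate has a complete derivatization chain: the ion
C15H23O11, i.e. the neutral C15H22O11. The eliminated rows say why each
competitor failed — no partner at some degree, or too few oxygens to
host four silylation sites.

The same operations are available as a library:

```python
import silylms as s

quercetin = s.parse_formula("C15H10O7")
tbdms = s.get_reagent("TBDMS")
species = s.derivatized_formula(quercetin, tbdms, 5)   # C45H80O7Si5
s.mz(species, s.ADDUCTS["[M+H]+"])                     # 873.4823
```

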