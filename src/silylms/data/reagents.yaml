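# Silylation reagent registry.
#
# site_delta is the NET composition change per derivatized site: the
# silyl group minus the acidic proton it replaces (so TBDMS adds
# C6H14Si = SiC6H15 - H, nominal +114; TMS adds C3H8Si, nominal +72).
# ei_losses are the characteristic radical losses seen under electron
# ionization (alpha-cleavage at silicon).  reporter_ion_mz is an
# optional low-mass diagnostic ion (the trimethylsilylium cation at
# m/z 73 for TMS chemistry).
TBDMS:
  site_delta: C6H14Si
  target_groups: [hydroxyl, thiol, amine]
  ei_losses:
    - [methyl, CH3]
    - [t-butyl, C4H9]
  reporter_ion_mz: null
TMS:
  site_delta: C3H8Si
  target_groups: [hydroxyl, thiol, amine]
  ei_losses:
    - [methyl, CH3]
  reporter_ion_mz: 73.0468
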