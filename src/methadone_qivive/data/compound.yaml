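# Physicochemical and ADME constants of the methadone enantiomers (free base).
# Absorption parameters are shared between enantiomers (no chiral difference
# reported for absorption); plasma protein binding and renal clearance are
# enantiomer specific.
mw_g_mol: 309.45
logp: 3.93
pka: 9.2                   # monoprotic base
blood_plasma_ratio: 0.7
ka_per_h: 0.59             # first-order oral absorption rate constant
fa: 0.88                   # oral fraction absorbed
fu_medium: 0.79            # unbound fraction in the hiPSC-CM assay medium
potency_ratio_s_over_r: 3.5  # hERG-block potency of S- relative to R-methadone
enantiomers:
  R:
    fu_p: 0.16             # fraction unbound in plasma
    rcl_l_h: 1.8           # renal clearance, L/h (blood basis)
  S:
    fu_p: 0.12
    rcl_l_h: 1.1
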