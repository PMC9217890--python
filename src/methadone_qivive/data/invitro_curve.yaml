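# Synthetic stand-in for the hiPSC-CM multi-electrode-array concentration-
# response curve of rac-methadone induced FPDc prolongation.  A Hill curve
# on nominal rac-methadone medium concentration; the maximal prolongation and
# the concentration range bracket the therapeutically relevant window so the
# reverse-dosimetry output lands on the scale of the reference analysis.
hill:
  emax_pct: 60.0
  ec50_um: 1.1
  n: 1.5
concentrations_um: [0.1, 0.3, 1.0, 3.0, 10.0, 30.0]
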