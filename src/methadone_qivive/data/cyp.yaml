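# Recombinant-CYP (Supersome) kinetic constants for EDDP formation, the
# inter-system extrapolation factors (ISEF) scaling them to human liver
# microsomes, and the hepatic CYP abundance distributions with phenotype
# frequencies.  The reported dissociation constant Ks is used as Km (rapid
# equilibrium assumption).  f_m,CYP is the fraction of total in vitro
# metabolic clearance carried by each isoform (Caucasian-derived values,
# also applied to the Chinese population).
fm_cyp:
  R: {CYP2B6: 0.44, CYP2C19: 0.09, CYP3A4: 0.46}
  S: {CYP2B6: 0.59, CYP2C19: 0.09, CYP3A4: 0.32}
isoform_kinetics:
  R:
    CYP2B6:  {vmax_pmol_min_pmol: 36.0, km_um: 60.0}
    CYP2C19: {vmax_pmol_min_pmol: 22.0, km_um: 97.0}
    CYP3A4:  {vmax_pmol_min_pmol: 43.0, km_um: 137.0}
  S:
    CYP2B6:  {vmax_pmol_min_pmol: 15.0, km_um: 16.0}
    CYP2C19: {vmax_pmol_min_pmol: 8.0,  km_um: 125.0}
    CYP3A4:  {vmax_pmol_min_pmol: 46.0, km_um: 149.0}
isef:
  Caucasian:
    R: {CYP2B6: 0.13,  CYP2C19: 0.10,  CYP3A4: 0.04}
    S: {CYP2B6: 0.13,  CYP2C19: 0.39,  CYP3A4: 0.03}
  Chinese:
    R: {CYP2B6: 0.072, CYP2C19: 0.047, CYP3A4: 0.0062}
    S: {CYP2B6: 0.049, CYP2C19: 0.13,  CYP3A4: 0.0034}
abundances:
  # mean abundance in pmol/mg microsomal protein; cv as a fraction.
  # For the Chinese CYP2C19 and CYP3A4 the extensive-metaboliser
  # distribution stands in for the whole population (frequency 1).
  Caucasian:
    CYP2B6:
      - {phenotype: EM, frequency: 0.89, mean_pmol_mg: 17.0, cv: 1.22}
      - {phenotype: PM, frequency: 0.11, mean_pmol_mg: 6.0,  cv: 2.00}
    CYP2C19:
      - {phenotype: general, frequency: 1.0, mean_pmol_mg: 11.0, cv: 0.82}
    CYP3A4:
      - {phenotype: general, frequency: 1.0, mean_pmol_mg: 93.0, cv: 0.81}
  Chinese:
    CYP2B6:
      - {phenotype: EM, frequency: 0.95, mean_pmol_mg: 5.3, cv: 1.98}
      - {phenotype: PM, frequency: 0.05, mean_pmol_mg: 1.9, cv: 2.00}
    CYP2C19:
      - {phenotype: EM, frequency: 1.0, mean_pmol_mg: 4.4, cv: 0.39}
    CYP3A4:
      - {phenotype: EM, frequency: 1.0, mean_pmol_mg: 120.0, cv: 0.33}
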