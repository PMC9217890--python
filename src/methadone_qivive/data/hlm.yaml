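# Descriptive statistics of apparent Vmax (nmol/min/mg microsomal protein),
# Km (uM) and catalytic efficiency (Vmax/Km * 1000, uL/min/mg) for EDDP
# formation measured in incubations with 25 Caucasian and 25 Chinese
# individual human liver microsome preparations.  SDs use the n-1 sample
# convention; fold = highest/lowest individual value.
n_individuals: 25
summaries:
  Caucasian:
    R: {mean_vmax: 0.40,  sd_vmax: 0.324, mean_km: 155.1, sd_km: 42.8,
        mean_eff: 2.87, sd_eff: 2.64, fold_vmax: 13, fold_km: 3, fold_eff: 19}
    S: {mean_vmax: 0.34,  sd_vmax: 0.319, mean_km: 111.3, sd_km: 44.2,
        mean_eff: 4.27, sd_eff: 5.54, fold_vmax: 17, fold_km: 4, fold_eff: 37}
  Chinese:
    R: {mean_vmax: 0.064, sd_vmax: 0.031, mean_km: 127.7, sd_km: 42.4,
        mean_eff: 0.55, sd_eff: 0.35, fold_vmax: 11, fold_km: 4, fold_eff: 10}
    S: {mean_vmax: 0.046, sd_vmax: 0.021, mean_km: 115.6, sd_km: 63.6,
        mean_eff: 0.47, sd_eff: 0.28, fold_vmax: 11, fold_km: 8, fold_eff: 12}
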