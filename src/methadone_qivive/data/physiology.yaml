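# Reference physiologies.  Caucasian values follow the standard reference-man
# compilation (Brown et al. style); Chinese values follow national reference
# survey data, with the arterial/venous blood volumes and the heart blood flow
# copied from the Caucasian reference because no Chinese values are available
# (they are non-influential parameters).  Volume fractions are fraction of
# body weight (1 kg tissue ~ 1 L); flow fractions are fraction of cardiac
# output and must sum to 1.  Cardiac output = coefficient * BW^0.74 (L/h).
populations:
  Caucasian:
    bw_kg: 70.0
    mppgl_mg_g: 32.0
    cardiac_output_l_h_per_kg074: 15.0
    volume_fractions:
      liver: 0.026
      heart: 0.005
      fat: 0.214
      richly: 0.05
      slowly: 0.54
      arterial: 0.0198
      venous: 0.0593
    flow_fractions:
      liver: 0.227
      heart: 0.04
      fat: 0.052
      richly: 0.30
      slowly: 0.381
  Chinese:
    bw_kg: 58.5
    mppgl_mg_g: 39.46
    cardiac_output_l_h_per_kg074: 15.0
    volume_fractions:
      liver: 0.0271
      heart: 0.005      # copied from Caucasian
      fat: 0.154
      richly: 0.05
      slowly: 0.566
      arterial: 0.0198  # copied from Caucasian
      venous: 0.0593    # copied from Caucasian
    flow_fractions:
      liver: 0.24
      heart: 0.04       # copied from Caucasian
      fat: 0.047
      richly: 0.293
      slowly: 0.38
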