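# Reference study outputs carried as packaged constants: chemical-specific
# adjustment factors (CSAF) from the multifactor Monte Carlo analysis (values
# for the metabolism-only scenario suffixed _metabolism), the benchmark-dose
# lower bounds of the reference dose-response analysis, and the therapeutic
# rac-methadone dosing stages used for margin-of-safety calculations.
csaf:
  R:
    caucasian: {p95: 2.4, p99: 3.1, p95_metabolism: 1.7, p99_metabolism: 2.0}
    chinese:   {p95: 1.9, p99: 2.5, p95_metabolism: 1.2, p99_metabolism: 1.3}
    combined:  {p95: 4.5, p99: 5.8, p95_metabolism: 3.0, p99_metabolism: 3.2}
  S:
    caucasian: {p95: 2.5, p99: 3.3, p95_metabolism: 1.9, p99_metabolism: 2.3}
    chinese:   {p95: 2.1, p99: 2.6, p95_metabolism: 1.3, p99_metabolism: 1.4}
    combined:  {p95: 6.7, p99: 8.3, p95_metabolism: 4.5, p99_metabolism: 4.7}
bmdl10_mg_day:
  R: {caucasian_average: 99.6, caucasian_sensitive: 32.4,
      chinese_average: 39.5,  chinese_sensitive: 15.8}
  S: {caucasian_average: 18.7, caucasian_sensitive: 5.5,
      chinese_average: 5.1,   chinese_sensitive: 1.9}
therapeutic_dose_mg_day: {initial: 10.0, maintenance: 60.0}
ipcs_default_kinetic_factor: 3.16
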