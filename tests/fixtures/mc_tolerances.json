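{
 "pilot_seed": 20250921,
 "n_replicates": 100,
 "rule": "1.5 * pilot p95 of |error|, rounded up to 2 significant digits",
 "tolerances": {
  "cavitation_E_relerr_tol": 0.014,
  "indentation_E_relerr_tol": 0.012,
  "saos_E_relerr_tol": 0.16,
  "saos_beta_abserr_tol": 0.069,
  "uniaxial_toe_relerr_tol": 0.34
 }
}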