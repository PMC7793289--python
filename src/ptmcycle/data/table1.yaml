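# Reference kinetic parameter sets (nM, s). kcat and K_M sit in
# experimentally observed ranges; delta1 corresponds to the average human
# protein half-life (log(2)/10 h) and delta2 to the fastest observed
# degradation rates. D_total = 0.1 nM; M_total is set through the input
# ratio r at scan time. "unsaturated" has K_M = 10 x [S]_T at [S]_T = 1e3 nM;
# "saturated_Q" reaches saturation by raising the synthesis rate Q
# ([S]_T = 1e5 nM); "saturated_KM" by lowering K_M to 1e2 nM at fixed Q.
unsaturated:
  k_plus_M: 1.0e-4
  k_minus_M: 1.0e-3
  kcat_M: 0.999
  k_plus_D: 1.0e-4
  k_minus_D: 1.0e-3
  kcat_D: 0.999
  Q: 2.0e-2
  delta1: 2.0e-5
  delta2: 2.0e-4
  M_total: 0.0
  D_total: 0.1
saturated_Q:
  k_plus_M: 1.0e-4
  k_minus_M: 1.0e-3
  kcat_M: 0.999
  k_plus_D: 1.0e-4
  k_minus_D: 1.0e-3
  kcat_D: 0.999
  Q: 2.0
  delta1: 2.0e-5
  delta2: 2.0e-4
  M_total: 0.0
  D_total: 0.1
saturated_KM:
  k_plus_M: 1.0e-2
  k_minus_M: 1.0e-3
  kcat_M: 0.999
  k_plus_D: 1.0e-2
  k_minus_D: 1.0e-3
  kcat_D: 0.999
  Q: 2.0e-2
  delta1: 2.0e-5
  delta2: 2.0e-4
  M_total: 0.0
  D_total: 0.1
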