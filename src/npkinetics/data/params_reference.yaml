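polymer:
  contour_per_nt: 0.56
  kuhn_length: 1.5
  stretch_modulus: null
  temperature: 294.15
  gamma_compact:
    10.0: 0.8
    30.0: 0.6
    50.0: 0.3
  gamma_decompact:
    10.0: 0.26666666666666666
    30.0: 0.19999999999999998
    50.0: 0.09999999999999999
  gamma_monomer:
    10.0: 0.26666666666666666
    30.0: 0.19999999999999998
    50.0: 0.09999999999999999
lattice:
  n_nt: 8100
  trimer_footprint: 50
  subunit_footprint: 17
  mode: WT
  suppress_decompaction_below_pN: 6.0
rates:
  k_b: 0.042
  k_c: 0.45
  k_bd: 0.02894736842105263
  k_dec_max: 0.15
  k_di0: 0.11
  K_r: 3.0
  k_df0: 0.006945525291828796
  tau_oligo: 100.0
  lambda_oligo: 11.0
  dx_df: 0.25
  dx_olig: 0.4
  k_b_mono: 0.014
  k_off_mono: 0.024
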