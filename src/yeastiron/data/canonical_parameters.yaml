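# Canonical optimized parameter set (uM, hr units throughout).
# shared: identical for both strains; strains: strain-specific overrides.
shared:
  alpha_max: 0.204
  K_N: 4.0
  sens: 2.0
  R_vac_max: 1140.0
  K_vac: 11.0
  nvac: 3.0
  R_cia_max: 56.0
  K_cia: 3.8
  ncia: 3.0
  R_isu_max: 180.0
  K_isu: 220.0
  nisu: 2.3
  nvp: 2.4
  k_23: 5.2
  FS_sp: 370.0
  n23: 1.6
  k_mp: 0.09
  k_O2: 25.0
  k_res: 9.0
  O2_cyt: 100.0
strains:
  WT:
    R_cell_max: 180.0
    R_cyt_max: 230.0
    K_alpha: 0.13
    k_mit_c3: 2.8
    k_mit: 5.5
    k_vp: 1.10e-7
  DD:
    R_cell_max: 390.0
    R_cyt_max: 480.0
    K_alpha: 3.9
    k_mit_c3: 1.6
    k_mit: 1.2
    k_vp: 2.37e-7
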