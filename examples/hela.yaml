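# HeLa-like cell freezing study: measured isotonic radius, pooled-fit
# membrane parameters, and nucleation parameters with critical volumes.
cell:
  radius_um: 7.51
  Vb_frac: 0.25
  Lpg_um_min_atm: 0.1166
  ELp_kcal_mol: 11.9236
nucleation:
  scn: {Omega0: 2.7e8, kappa0: 3.5e9, Vf_frac: 0.50}
  vcn: {Omega0: 3.0e18, kappa0: 8.0e10, Vf_frac: 0.40}
protocol:
  T_start_C: -0.5
  T_end_C: -50.0
  rates_C_min: [45.0, 60.0, 75.0, 100.0]
synthetic:
  seed: 1
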