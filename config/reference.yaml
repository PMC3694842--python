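params:
  nf_tot: 200.0
  c0: 0.00185
  c1: 220.0
  deg_a: 0.009
  r_ikk: 0.384
  rho: 1.0
  kp: 218.9
  kc: 9.1
  tau1: 45.0
  tau2: 45.0
  eps: 0.64
  c0_e: 0.0002
  deg_e: 1.15
  constitutive_only: false
signal:
  amplitude: 1.0
  t_on: 0.0
  duration: inf
  baseline: 0.0
integrator:
  rel_tol: 1.0e-08
  abs_tol: 1.0e-10
  max_step: 5.0
  disc_depth: 2
t_end: 600.0
tau2_grid:
- 0.0
- 7.5
- 15.0
- 22.5
- 30.0
- 37.5
- 45.0
- 52.5
- 60.0
- 67.5
- 75.0
- 82.5
- 90.0
eps_grid:
- 0.0
- 0.1
- 0.2
- 0.30000000000000004
- 0.4
- 0.5
- 0.6000000000000001
- 0.7000000000000001
- 0.8
- 0.9
- 1.0
k_grid:
- 0.25
- 0.5
- 1.0
- 2.0
- 4.0
pulse_durations:
- 15.0
- 30.0
- 45.0
- 60.0
- 90.0
- 120.0
threshold: 50.0
n_nfkb_total: 1000
n_runs: 200
seed: 0
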