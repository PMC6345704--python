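# Frozen default configuration. All experiments and regression numbers
# refer to this single parameter set; editing it invalidates them.
model:
  alpha_a: 25.0
  alpha_r: 1.0
  alpha_v: 0.25
  alpha_n: 4.0
  alpha_c: 5.0
  alpha_e: 0.5
  sigma_a: 1.0
  eps_v: 0.01
  sigma_n: 1.0
  sigma_sa: 0.5
  sigma_sx: 0.5
  sigma_rp: 0.03
  n_scales: 2
  mu: 1.4142135623730951
  lam_c: 3.0
  lobe_across: 0.8
  delta_c: 0.0
  kappa_concave: 3.0
  kappa_smax: 200.0
  L: 12
multipliers:
  sb0: 1.0
  sbs: 2.0
  sx0: 1.0
  sxs: 1.0
  sr0: 1.0
  srs: 0.5
schedule:
  s0: 1.0
  s_r: 0.5
  s_m: 0.13
descent:
  max_iter: 80
  tol: 1.0e-06
  tol_streak: 3
  step_init: 1.0
  step_growth: 2.0
  max_backtracks: 25
  grad_floor: 1.0e-12
final_descent:
  max_iter: 200
  tol: 1.0e-07
  tol_streak: 3
  step_init: 1.0
  step_growth: 2.0
  max_backtracks: 25
  grad_floor: 1.0e-12
repulsion:
  rho: 2.0e-03
  d_t: 0.03
  eps_rep: 0.01
  tau: 4.0
  tau_max: 4.0
  max_interpretations: 4
  max_cost_excess: 0.2
contour:
  v: 1.0
  R: 3.0
  sigma_q: 0.5
  g_t: 0.5
  seed_radius: 2.0
  curvature_weight: 0.3
  max_steps: 500
  reinit_every: 20
  stall_window: 50
  stall_fraction: 0.001
seed: 17
illusory_fraction_threshold: 0.02
version: "1.0"
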