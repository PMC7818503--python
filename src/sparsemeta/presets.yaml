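# Scenario presets for the arm-level heterogeneity simulator.
#
# paper_full_factors crosses every factor level of the simulation design:
# trials k, per-arm sample-size range, control event rate pi_c,
# between-study SD tau and overall log odds ratio delta (162 cells).
#
# desk_small is a 12-cell subset sized for a single workstation: the two
# extreme trial counts and both sample-size regimes at the sparsest control
# event rate, with (tau, delta) spanning the no-heterogeneity null, a
# moderate case, and the hardest high-heterogeneity large-effect corner.
paper_full_factors:
  k: [2, 4, 6]
  n_range: [[5, 10], [40, 50]]
  pi_c: [0.05, 0.1, 0.3]
  tau: [0.01, 0.5, 1.0]
  delta: [0.0, 0.5, 3.0]
  n_reps: 1000
desk_small:
  k: [2, 6]
  n_range: [[5, 10], [40, 50]]
  pi_c: [0.05]
  tau_delta: [[0.01, 0.0], [0.5, 0.5], [1.0, 3.0]]
  n_reps: 200
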