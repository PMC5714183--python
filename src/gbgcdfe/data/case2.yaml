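# Strong purifying selection plus rare, weakly beneficial mutations.
label: case2
dfe:
  beta: 0.3
  mean_gamma: -2000.0
  beneficial_fraction: 0.005
  beneficial_gamma: 3.0
context:
  theta: 0.01
  kappa: 2.0
  gc_content: 0.472
  n: 50
B_grid: [0.0, 1.0, 3.0, 5.0, 10.0]
n_neutral_sites: 5.0e+6
n_selected_sites: 5.0e+6
t_theta: 1.0
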