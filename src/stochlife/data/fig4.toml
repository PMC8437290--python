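# Two-resource utilization study: risky resource R1 (b1, sigma1) vs safe
# resource R2 (b2, sigma2); shared demography as in fig2.toml.

[model]
b1 = 0.6
b2 = 0.5
sigma1 = 0.8
sigma2 = 0.005
x = 0.01
mu0 = 0.1
f0 = 1.0
rho = 0.4

[environment]
epsilon = 0.0
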