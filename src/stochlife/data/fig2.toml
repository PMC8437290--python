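# Adaptive-heterogeneity study: GBM size growth with allometric fertility.
# sigma1 is the swept quantity; 0.5 is the reference value used by the
# spectral fixtures.

[model]
b1 = 0.6
sigma1 = 0.5
x = 0.01
mu0 = 0.1
f0 = 1.0
rho = 0.4

[environment]
epsilon = 0.0
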