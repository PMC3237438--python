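# Expanded-growth-model parameter set calibrated for corn at Florence, SC (1982 season).
# Units: mu, sigma_sqrt2 in weeks since Jan. 1; c in 1/wk; k, x_i dimensionless.
mu = 26.0
sigma_sqrt2 = 8.0
c = 0.2
k = 5.0
x_i = 0.0
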