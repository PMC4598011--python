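# glymphsim parameter preset: ApoE4 (flat keys = ModelParams fields)
d = 0.01  # fraction/yr
k1 = 0.034  # fraction/yr
k2 = 0.01  # fraction/yr
k3 = 16000.0  # molecules/neuron/day
k8 = 3000.0  # molecules/neuron/day
k4 = 1.5  # dimensionless
k5 = 1400.0  # molecules/microglia/day
k11 = 200.0  # molecules/microglia/day
k6 = 0.12  # fraction/day
k7 = 0.004  # fraction/day
k9a = 0.002  # fraction/day
k7a = 0.001  # fraction/day
k9 = 0.001  # fraction/day
k10 = 0.01  # fraction/yr
k12 = 7.3e-05  # fraction/day
N0 = 5275.0  # count
M0 = 4500.0  # count
EC0 = 22050.0  # count
LRP0 = 930000000000.0  # count
C1_0 = 450.0  # pg/mL
C4_0 = 70.0  # pg/mL
pvs_init_fraction = 0.1  # dimensionless
v0 = 0.2945627  # mm/day (calibrated)
k_exit = 0.1304205  # fraction/day (calibrated)
theta_k1 = 20.0  # multiples of initial C1
mw40 = 4330.0  # Da
mw42 = 4514.0  # Da
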