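N_E: 8
N_I: 2
J_EE: 10.0
J_EI: -70.0
J_IE: 70.0
J_II: -10.0
tau_E: 1.0
tau_I: 1.0
nu_max_E: 1.0
nu_max_I: 1.0
Lambda_E: 2.0
Lambda_I: 2.0
V_T_E: 2.0
V_T_I: 2.0
I_E: 0.0
I_I: 0.0
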