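# COI preset: TrN+I+G parameter set for the darwinulid COI fragment,
# expressed in the general GTR parameterisation (rates in order
# AC, AG, AT, CG, CT, GT; GT fixed at 1 by convention).
freqs: [0.34, 0.26, 0.11, 0.28]
rates: [1.00, 4.30, 1.00, 1.00, 10.87, 1.00]
p_inv: 0.58
gamma_shape: 1.57
categories: 4
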