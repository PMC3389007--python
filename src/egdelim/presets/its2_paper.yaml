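# ITS2 preset: TPM2uf+G parameter set for the darwinulid ITS2 region,
# expressed in the general GTR parameterisation (rates in order
# AC, AG, AT, CG, CT, GT).
freqs: [0.13, 0.30, 0.33, 0.23]
rates: [2.36, 4.61, 2.36, 1.00, 4.61, 1.00]
p_inv: 0.0
gamma_shape: 0.45
categories: 4
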