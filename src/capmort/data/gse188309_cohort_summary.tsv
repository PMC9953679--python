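quantity	count
n_admitted	228
n_died	18
n_comorbidities	154
n_psi_high_risk	146
n_arrays_processed	198
n_arrays_died	13
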