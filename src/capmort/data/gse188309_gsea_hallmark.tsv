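gene_set	nom_p	fdr_q	NES
HALLMARK_SPERMATOGENESIS	0.000	0.034	1.66
HALLMARK_INTERFERON_ALPHA_RESPONSE	0.011	0.202	1.44
HALLMARK_P53_PATHWAY	0.016	0.237	1.39
HALLMARK_G2M_CHECKPOINT	0.020	0.199	1.37
HALLMARK_MYC_TARGETS_V1	0.000	0.000	-2.13
HALLMARK_OXIDATIVE_PHOSPHORYLATION	0.000	0.005	-1.80
HALLMARK_MYC_TARGETS_V2	0.000	0.010	-1.67
HALLMARK_UNFOLDED_PROTEIN_RESPONSE	0.000	0.010	-1.65
HALLMARK_ALLOGRAFT_REJECTION	0.000	0.051	-1.45
HALLMARK_ANGIOGENESIS	0.072	0.076	-1.39
HALLMARK_REACTIVE_OXYGEN_SPECIES_PATHWAY	0.139	0.241	-1.24
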