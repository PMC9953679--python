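characteristic	died_n	survived_n
male_sex	12	124
current_smoker	2	41
copd	4	68
chronic_heart_disease	9	73
diabetes_mellitus	6	43
fever	3	81
tachycardia	11	124
impaired_consciousness	3	29
septic_shock	5	12
respiratory_failure	15	115
leukocytosis	12	124
multilobar_pneumonia	6	65
bacteremia	3	16
bacterial_pneumonia	6	76
pneumococcal_pneumonia	3	45
viral_pneumonia	1	11
psi_high_risk	17	129
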