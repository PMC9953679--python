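Symbol	p-Value	FoldChange	Resampling_N
SCRG1	0.001	1.28	383
FAM72A	0.001	1.45	363
KCNK16	0.001	1.20	270
SLC26A10	0.001	1.25	267
ZNF563	0.001	1.18	448
OTUD7B	0.002	1.20	339
ADCK4	0.004	1.16	533
F2RL2	0.004	1.18	337
GTPBP6	0.004	-1.13	286
TBKBP1	0.004	1.35	365
HHIPL2	0.005	1.14	346
PLXNA1	0.005	-1.13	339
SPATA5	0.006	-1.18	418
NRL	0.006	1.17	317
UBE2S	0.006	1.18	268
MFSD9	0.007	1.28	327
OXR1	0.007	1.24	257
DIXDC1	0.007	1.23	344
SH3D21	0.009	-1.16	337
PGAP2	0.009	1.18	265
FOS	0.009	1.19	318
ZFYVE21	0.009	1.18	261
HS6ST1	0.009	1.12	258
BTBD8	0.012	1.22	315
RIMKLB	0.012	1.19	312
EBF4	0.012	-1.14	428
METTL20	0.013	1.16	293
EIF4G2	0.016	-1.15	279
CACNA1S	0.018	-1.14	304
TM4SF1	0.023	-1.19	357
ZNF311	0.023	-1.12	268
HLA-DQA2	0.026	-1.24	255
ESPL1	0.028	1.12	266
BUD31	0.030	1.17	283
CCND3	0.031	1.34	318
GINS1	0.031	1.19	262
ASXL1	0.031	1.21	404
C10orf54	0.033	1.18	403
AURKA	0.034	1.18	332
ZNF506	0.035	1.13	267
CASC5	0.035	1.18	261
AIG1	0.039	-1.17	303
SPRYD3	0.039	1.13	391
CDC42	0.039	-1.09	323
ZBTB37	0.041	1.19	258
CAMP	0.043	-1.46	304
CCDC183	0.044	1.10	343
COQ6	0.046	1.13	252
CENPE	0.049	1.16	312
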