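no	name	logp_exp	iset	delta_iset	delta_ghose_crippen	delta_alogp	delta_clogp	delta_mlogp	flags
01	1-Undecanol	4.42	12.3394	-0.22	0.7	0.26	-0.18	0.32
02	2-Undecanol	4.42	11.7816	0.14	0.6	0.33	-0.12	0.32
03	4-Octanol	2.68	9.2504	0.02	0.06	-0.1	-0.47	0.41
04	2-Methyl-1-butanol	1.14	7.2774	-0.26	-0.2	-0.15	-0.55	-0.07
05	2-Methyl-3-hexanol	2.19	8.2667	0.16	-0.04	0.0	-0.37	0.25
06	2.3-Dimethyl-3-pentanol	1.67	7.78	-0.05	-0.24	-0.27	-0.58	-0.27
07	4.4-Dimethyl-1-pentanol	2.39	8.6815	0.09	0.29	0.51	-0.28	0.45
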