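class	method	n	a	b	r2	r	f	s	rcv2	flags
hydrocarbon	ghose_crippen	23	-0.0740	1.3559	0.9925	0.9962	2760.8	0.1694	0.9907
hydrocarbon	alogp	23	0.3080	1.1554	0.9952	0.9976	4345.4	0.1352	0.9940
hydrocarbon	clogp	23	0.1451	1.1513	0.9923	0.9961	2694.0	0.1715	0.9904
hydrocarbon	mlogp	23	-0.0923	1.2953	0.9565	0.9780	462.2	0.4066	0.9494
hydrocarbon	iset	23	0.0039	0.9997	0.9971	0.9986	7289	0.1045	0.9964
alcohol	ghose_crippen	60	-0.6651	1.3623	0.9822	0.9911	3202.8	0.2196	0.9813
alcohol	alogp	60	-0.3038	1.1600	0.9897	0.9949	5592.7	0.1668	0.9893
alcohol	clogp	60	-0.7966	1.1550	0.9914	0.9957	6651.4	0.1531	0.9910
alcohol	mlogp	60	-0.4666	1.3344	0.9611	0.9803	1431.6	0.3249	0.9561
alcohol	iset	60	-3.2482	0.6394	0.9876	0.9938	4612.6	0.1835	0.9870	decimal_comma_normalized;intercept_sign_normalized;x_is_raw_iset
aldehyde	ghose_crippen	9	0.2243	1.2357	0.9539	0.9767	145.0	0.2318	0.9134
aldehyde	alogp	9	-0.2236	1.0954	0.9789	0.9894	324.6	0.1611	0.9613
aldehyde	clogp	9	-0.6533	1.1187	0.9979	0.9990	3388.8	0.0503	0.9966
aldehyde	mlogp	9	0.1668	1.0159	0.9489	0.9741	130.0	0.2566	0.8469
aldehyde	iset	9	0.0016	1.0014	0.9972	0.9986	2525.9	0.0583	0.9961
ketone	ghose_crippen	19	-0.8484	1.2097	0.9188	0.9585	192.3	0.3861	0.8867
ketone	alogp	19	-0.1299	1.1494	0.9862	0.9931	1213.4	0.1593	0.9829
ketone	clogp	19	-0.8479	1.1132	0.9115	0.9547	175.1	0.4031	0.8974
ketone	mlogp	19	-0.2586	1.1454	0.9694	0.9846	538.8	0.2370	0.9622
ketone	iset	19	-2.7182	0.6693	0.9864	0.9932	1229.7	0.1582	0.9831	x_is_raw_iset
ester	ghose_crippen	14	0.3894	1.1472	0.9688	0.9843	372.9	0.2124	0.9573
ester	alogp	14	0.1815	1.1080	0.9681	0.9839	364.7	0.2147	0.9590
ester	clogp	14	-0.3054	1.1334	0.9943	0.9971	2076.6	0.0912	0.9928
ester	mlogp	14	0.1370	1.1742	0.9851	0.9925	791.6	0.1470	0.9630
ester	iset	14	-3.1575	0.6587	0.9903	0.9951	1222.9	0.1186	0.9838	x_is_raw_iset
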