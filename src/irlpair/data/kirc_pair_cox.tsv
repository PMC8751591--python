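pair	coefficient	hr	hr_low	hr_high	p_value
AC003070.1|LINC01355	-0.3288	0.719785	0.500928	1.034261	0.075434
AC007098.1|AL513218.1	-0.30849	0.734555	0.492259	1.09611	0.13089
AC007098.1|AC093788.1	-0.52659	0.590616	0.391629	0.890708	0.012002
AC093001.1|MCF2L-AS1	0.677176	1.968312	1.404197	2.759052	8.49E-05
AC103563.7|AL031123.1	0.339006	1.403552	1.021037	1.929371	0.03678
HOXB-AS3|AC027796.4	-0.47882	0.619511	0.382477	1.003444	0.051656
SMIM25|AC008105.3	-0.47275	0.623284	0.40096	0.968881	0.035692
SEMA6A-AS1|AC084876.1	0.406183	1.501078	0.987318	2.282178	0.0574
SEMA6A-AS1|CR936218.1	-0.41778	0.658509	0.425095	1.020089	0.06136
SEMA6A-AS1|AC104564.3	-0.38017	0.683744	0.464403	1.006684	0.054078
LINC00861|AC084876.1	-0.31441	0.730217	0.488926	1.090588	0.124475
AC079015.1|AC093788.1	-0.42386	0.654517	0.451517	0.948784	0.025254
AC084876.1|AC100830.2	0.575764	1.778489	1.161522	2.723171	0.008078
AC084876.1|AC009704.2	0.67463	1.963306	1.390942	2.771194	0.000125
ARHGAP27P1-BPTFP1-KPNA2P3|AC116914.2	-0.41481	0.660465	0.474051	0.920182	0.014223
LINC00893|AC027796.4	-0.3658	0.693642	0.450763	1.06739	0.096231
AC011462.4|MMP25-AS1	0.320517	1.37784	0.975717	1.945689	0.068706
AL031710.1|MCF2L-AS1	-0.36667	0.693035	0.496767	0.966848	0.030895
AL662844.3|LINC01094	0.53578	1.70878	1.055544	2.766279	0.029265
AL662844.3|ITGB2-AS1	-1.04623	0.351258	0.21793	0.566157	1.74E-05
AC023669.2|AC063965.2	-0.31732	0.728096	0.516044	1.027285	0.070809
AL022322.1|AC020907.4	-0.30121	0.739923	0.531166	1.030724	0.074908
AC005785.1|AC063965.2	0.581787	1.789233	1.194042	2.681107	0.004812
AC005785.1|AC004585.1	0.656907	1.928817	1.309024	2.842067	0.000895
AC005104.1|AL031714.1	0.567601	1.76403	1.081279	2.877891	0.023033
AC100830.2|AC006435.2	1.167458	3.213814	2.075641	4.976102	1.66E-07
AC012615.6|AC008870.2	-0.56878	0.566217	0.383901	0.835116	0.004121
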