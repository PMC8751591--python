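lncRNA	normal_mean	tumor_mean	log_fc	p_value	fdr
AC104984.5	3.682574	0.462925451	-2.99186	3.54E-38	2.04E-36
AC015911.3	0.100497	0.821778506	3.0316	7.92E-31	8.18E-30
PTOV1-AS2	0.642868	2.771483237	2.108063	1.53E-18	5.01E-18
AC003070.1	0.283999	1.390484124	2.291631	2.55E-23	1.27E-22
AC020913.3	0.074073	0.617973411	3.060524	1.27E-13	2.62E-13
AD001527.1	0.127594	0.576003883	2.174521	4.91E-13	9.69E-13
AC004687.1	0.090107	0.986754328	3.452974	5.85E-29	5.24E-28
AC007098.1	0.106151	0.572507398	2.431175	2.41E-28	1.87E-27
AC093001.1	0.011144	0.965969528	6.437666	2.11E-10	3.40E-10
AC103563.7	5.173696	0.597977578	-3.11303	1.51E-36	4.93E-35
HOXB-AS3	5.586956	0.94096728	-2.56985	6.02E-36	1.62E-34
AL021707.6	0.457954	1.920309814	2.068065	1.75E-18	5.68E-18
AL590764.1	0.15393	0.753471696	2.291277	3.26E-31	3.46E-30
SMIM25	0.25703	1.518804932	2.562927	6.13E-33	8.52E-32
TRG-AS1	0.110214	0.712890989	2.69338	1.82E-35	4.08E-34
PRDM16-DT	13.2686	0.316471521	-5.3898	2.97E-40	3.99E-38
TRBV11-2	0.139708	0.8630982	2.627106	5.48E-19	1.87E-18
AL049555.1	3.540425	0.370257526	-3.25732	5.29E-36	1.52E-34
SEMA6A-AS1	0.144724	0.740373342	2.354945	1.72E-27	1.24E-26
AC091185.1	0.171909	0.846735721	2.300265	7.20E-24	3.72E-23
AL021707.7	0.12328	0.576657008	2.225772	5.35E-17	1.43E-16
AL513327.1	0.253827	1.052985268	2.05257	1.35E-24	7.65E-24
LINC00861	0.089858	0.728956024	3.02011	1.93E-31	2.18E-30
AC079015.1	0.069813	0.732073012	3.390413	1.14E-33	1.77E-32
AC084876.1	0.082949	0.572314341	2.78651	1.30E-24	7.46E-24
AC127024.4	0.250425	1.055792994	2.075876	3.21E-17	8.87E-17
AC010973.2	0.170749	0.775083366	2.182473	4.60E-24	2.44E-23
AC023421.1	10.33512	0.109043989	-6.5665	2.25E-34	3.94E-33
ARHGAP27P1-BPTFP1-KPNA2P3	0.317314	1.367695028	2.107763	9.89E-23	4.69E-22
AL513218.1	0.142618	0.595938402	2.063012	4.51E-15	1.02E-14
CR936218.1	0.259281	1.093931575	2.076936	9.57E-22	4.10E-21
PCED1B-AS1	0.477539	3.126144012	2.710694	7.88E-36	1.92E-34
FOXC2-AS1	0.099379	0.724179466	2.865338	9.22E-13	1.79E-12
LINC00893	0.168803	0.800961054	2.246392	9.65E-17	2.51E-16
LINC02084	0.147412	0.832738092	2.498013	9.70E-27	6.51E-26
AC011462.4	0.384346	1.66693917	2.116724	2.50E-18	7.88E-18
AL031710.1	10.23424	1.697657813	-2.59179	5.68E-33	8.17E-32
AC004921.1	0.13765	0.704239881	2.355067	2.66E-34	4.28E-33
AC008735.2	0.609316	3.237210057	2.409489	7.61E-20	2.71E-19
MCF2L-AS1	2.411878	0.498237863	-2.27525	1.59E-36	4.93E-35
AL662844.3	0.115057	0.989206462	3.103922	2.20E-28	1.74E-27
IGFL2-AS1	0.021451	0.827439957	5.269534	2.01E-07	2.79E-07
AC023669.2	0.277618	1.903775796	2.777691	0.000737	0.000869
AL135999.1	0.211246	0.893068672	2.079847	7.64E-17	2.00E-16
AP000757.1	8.871118	1.183177983	-2.90645	1.56E-36	4.93E-35
AL022322.1	0.196393	1.37638469	2.809066	8.38E-24	4.28E-23
AC104564.3	0.177313	0.780916828	2.138872	7.16E-18	2.15E-17
AC004253.1	0.148081	0.831291733	2.488964	5.64E-22	2.47E-21
USP30-AS1	0.394299	2.072622237	2.394094	1.15E-28	9.68E-28
LINC01355	0.246017	1.126133673	2.19455	1.08E-20	4.17E-20
AC004923.4	0.157851	0.649031036	2.039724	3.03E-22	1.41E-21
AC019197.1	2.144548	0.331330829	-2.69433	2.06E-35	4.31E-34
FAM13A-AS1	0.216505	1.241791946	2.519949	1.42E-29	1.33E-28
AC093788.1	0.138316	0.584969989	2.080399	3.62E-19	1.25E-18
HCG27	0.202245	1.578450713	2.964331	3.72E-32	4.68E-31
AC016773.2	0.107834	0.677946827	2.652365	1.23E-20	4.70E-20
AC092119.2	0.153225	0.65949918	2.105717	8.33E-15	1.86E-14
AC148477.4	5.974009	0.803677607	-2.89401	2.37E-34	3.98E-33
AC005785.1	0.121053	0.610457023	2.334251	9.01E-29	7.89E-28
AC027796.4	0.224249	1.066627441	2.24988	1.74E-17	4.93E-17
AC245884.8	0.222197	1.305749985	2.554966	1.03E-21	4.38E-21
AC005104.1	0.290904	1.230954211	2.081162	1.63E-19	5.75E-19
AC009549.1	0.273816	1.404515616	2.358792	1.63E-31	1.99E-30
AP006621.2	0.441335	1.854161375	2.07082	3.74E-14	8.01E-14
AC100830.2	0.236398	0.996619494	2.075825	1.22E-17	3.56E-17
LINC01612	3.150561	0.338202929	-3.21965	2.61E-46	1.05E-43
AL353152.1	2.991248	0.17047375	-4.13313	2.50E-39	1.75E-37
AL035661.1	29.66428	2.555782522	-3.53689	1.54E-36	4.93E-35
AC012615.6	0.180508	0.82261601	2.188153	7.62E-23	3.65E-22
MALAT1	15.83501	71.62380448	2.177322	3.77E-10	5.96E-10
AL031123.1	10.58834	0.906174056	-3.54654	1.09E-39	1.09E-37
AC135050.3	0.160602	1.482246649	3.206223	1.68E-30	1.65E-29
AC006435.2	0.201304	0.937788214	2.219884	2.41E-15	5.55E-15
LINC01094	0.27725	1.963631257	2.824262	6.62E-37	2.96E-35
AC008870.2	0.140459	0.60869582	2.11557	5.25E-22	2.33E-21
AC009704.2	0.150205	0.940764575	2.646897	1.69E-20	6.36E-20
AC243960.1	0.190792	0.90584361	2.24726	2.19E-28	1.74E-27
AC008105.3	0.051766	0.825717921	3.995577	4.20E-33	6.28E-32
AC130469.1	0.057492	0.584918994	3.346804	2.14E-19	7.51E-19
AC116914.2	0.23694	1.374503075	2.536315	1.69E-22	7.93E-22
AL031714.1	0.188508	0.798453427	2.082584	1.83E-24	1.03E-23
AC020907.4	0.134378	1.094545179	3.025967	1.54E-25	1.00E-24
MMP25-AS1	0.315379	1.680744965	2.41394	8.09E-36	1.92E-34
AC063965.2	0.111037	0.705899432	2.668423	2.30E-17	6.49E-17
AL157392.4	0.134044	0.566137711	2.078443	1.63E-15	3.77E-15
ITGB2-AS1	0.223036	1.665270736	2.900407	2.01E-29	1.84E-28
AC015819.2	0.090653	0.645324543	2.831606	8.37E-26	5.53E-25
LINC00342	0.591509	3.152218235	2.413896	6.71E-27	4.58E-26
AC004585.1	0.089846	0.922131089	3.359442	2.00E-31	2.18E-30
MIR200CHG	2.760587	0.476473591	-2.53451	1.27E-41	2.56E-39
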