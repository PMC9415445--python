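# Published reference statistics for a COPD rat model treatment study:
# 16 genes significantly altered model-vs-control (six replicates per group,
# pooled-variance Student t, df = 10), with per-treatment p-values
# (BYF, BJF, YZF, APL herbal/drug protocols vs model) and the printed counts
# of treatments below each p threshold.
gene	fc	t	p	p_BYF	p_BJF	p_YZF	p_APL	num_p_lt_0.05	num_p_lt_0.1	num_p_lt_0.2
Dhx16	0.530623	-3.72567	0.003938	0.701224	5.52E-09	0.097164	5.50E-05	2	3	3
Upf2	1.039416	3.475603	0.005965	0.027316	0.011337	0.058669	0.02064	3	4	4
Uqcrc2	1.015124	3.212685	0.00929	0.022126	0.043653	0.93704	0.822763	2	2	2
Rhobtb3	0.884189	-3.09422	0.011362	0.78651	0.197268	0.106184	0.211585	0	0	2
Znhit3	1.012759	3.046952	0.012316	0.560379	0.689214	0.271842	0.713968	0	0	0
Denr	1.013586	3.017057	0.01296	0.010532	0.020327	0.118537	0.100091	2	2	4
Notch3	0.975045	-2.97443	0.01394	0.475693	0.000212	0.088364	0.020111	2	3	3
Sdhc	0.984546	-2.5892	0.026987	0.728516	0.001616	0.317634	0.000346	2	2	2
Dyrk2	0.923138	-2.53068	0.029836	0.718672	0.000155	0.19656	0.000206	2	2	3
Sec61a1	1.039209	2.52876	0.029934	0.202428	0.056216	0.006779	0.014547	2	3	3
Hmmr	0.688459	-2.48504	0.032263	0.994814	0.124428	0.03643	0.016983	2	2	3
Exosc7	0.943282	-2.48184	0.032441	0.492618	0.000315	0.509816	0.000261	2	2	2
Sh3gl3	0.718159	-2.42208	0.035933	0.36409	0.814336	0.458153	0.089266	0	1	1
Noa1	0.971469	-2.28776	0.045186	0.138333	0.00598	0.351014	0.173025	1	1	3
Trrap	1.043465	2.252802	0.047951	0.656511	0.036755	0.571989	0.012966	2	2	2
Plk4	0.857672	-2.24158	0.048873	0.547285	0.018171	0.724516	0.011406	2	2	2
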