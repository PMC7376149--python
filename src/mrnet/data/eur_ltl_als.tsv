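snp_id	gene	chrom	pos	a1	a2	beta_ltl	se_ltl	p_ltl	n_ltl	beta_als	se_als	p_als	n_als	pve	f_stat
rs11125529	TERT	2	54329370	C	A	-0.056	0.010	4.48E-08	37653	-0.007	0.020	0.730	80610	8.32E-04	31.4
rs10936599	TERC	3	170974795	T	C	-0.079	0.008	2.54E-31	37669	0.003	0.016	0.839	80610	3.89E-03	147.0
rs7675998	ZNF208	4	164227270	A	G	-0.074	0.009	4.35E-16	34694	-0.005	0.016	0.747	80610	1.94E-03	67.6
rs2736100	NAF1	5	1339516	A	C	-0.078	0.009	4.38E-19	25842	0.010	0.014	0.493	80610	2.90E-03	75.1
rs9420907	ACYP2	10	105666455	A	C	-0.069	0.010	6.90E-11	37653	0.050	0.019	0.011	80610	1.26E-03	47.6
rs8105767	RTEL1	19	22007281	A	G	-0.048	0.008	1.11E-09	37499	0.006	0.015	0.683	80610	9.59E-04	36.0
rs755017	OBFC1	20	61892066	A	G	-0.062	0.011	6.71E-09	37113	-0.005	0.022	0.831	80610	8.55E-04	31.8
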