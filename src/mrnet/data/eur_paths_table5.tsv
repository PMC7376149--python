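pop	exposure	mediator	outcome	a	se_a	p_a	b	se_b	p_b	c	se_c	p_c
EUR	LTL	HDL	ALS	0.082	0.029	0.005	0.013	0.039	0.743	0.097	0.089	0.274
EUR	LTL	LDL	ALS	-0.060	0.031	0.057	-0.110	0.031	3.41E-04	0.097	0.089	0.274
EUR	LTL	TC	ALS	-0.059	0.031	0.052	-0.098	0.032	0.002	0.097	0.089	0.274
EUR	LTL	TG	ALS	-0.095	0.028	0.001	-0.045	0.044	0.309	0.097	0.089	0.274
EUR	LTL	HDL	FTD	0.082	0.029	0.005	-0.035	0.125	0.786	-0.208	0.308	0.498
EUR	LTL	LDL	FTD	-0.060	0.031	0.057	-0.139	0.107	0.196	-0.208	0.308	0.498
EUR	LTL	TC	FTD	-0.059	0.031	0.052	-0.142	0.104	0.172	-0.208	0.308	0.498
EUR	LTL	TG	FTD	-0.095	0.028	0.001	-0.018	0.140	0.898	-0.208	0.308	0.498
Asian	LTL	HDL	ALS	-0.020	0.022	0.366	0.108	0.129	0.404	-0.284	0.180	0.116
Asian	LTL	LDL	ALS	0.003	0.023	0.898	-0.234	0.131	0.073	-0.284	0.180	0.116
Asian	LTL	TC	ALS	-0.002	0.014	0.911	-0.276	0.214	0.197	-0.284	0.180	0.116
Asian	LTL	TG	ALS	0.018	0.014	0.214	0.160	0.195	0.414	-0.284	0.180	0.116
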