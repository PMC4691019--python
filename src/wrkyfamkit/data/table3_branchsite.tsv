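hypothesis	lnL	p0	p1	p2a	p2b	omega0_background	omega0_foreground	omega1_background	omega1_foreground	omega2a_background	omega2a_foreground	omega2b_background	omega2b_foreground	two_delta_lnl
alternative	-9212.750	0.36828	0.56715	0.02542	0.03915	0.17271	0.17271	1	1	0.17271	999	1	999	35.237
null	-9230.368	0.31965	0.45639	0.09225	0.13171	0.17495	0.17495	1.00000	1.00000	0.17495	1.00000	1.00000	1.00000	
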