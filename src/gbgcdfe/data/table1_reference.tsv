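case	B	true_alpha_wwss	true_alpha_all	true_omega_wwss	true_omega_all	beta_hat	mean_gamma_hat	alpha_hat	omega_hat
case1	0	0	0	0	0	0.303	-197.3	0.0108	0.0018
case1	1	0	0	0	0	0.304	-196.4	0.0216	0.0036
case1	3	0	0	0	0	0.295	-209.1	0.0590	0.0106
case1	5	0	0	0	0	0.279	-231.5	0.0893	0.0175
case1	10	0	0	0	0	0.244	-292.5	0.1306	0.0305
case2	0	0.1588	0.1588	0.0158	0.0158	0.303	-1938.0	0.1685	0.0167
case2	1	0.1588	0.1573	0.0158	0.0157	0.304	-1921.8	0.1756	0.0175
case2	3	0.1588	0.1255	0.0158	0.0129	0.298	-2072.3	0.1816	0.0187
case2	5	0.1588	0.0960	0.0158	0.0104	0.286	-2369.3	0.1865	0.0202
case2	10	0.1588	0.0641	0.0158	0.0080	0.259	-3316.2	0.2065	0.0257
case3	0	0.4442	0.4442	0.3000	0.3000	0.2017	-40.0	0.4478	0.3025
case3	1	0.4442	0.4479	0.3000	0.3058	0.2027	-40.0	0.4557	0.3111
case3	3	0.4442	0.3882	0.3000	0.2502	0.1930	-42.9	0.4099	0.2642
case3	5	0.4442	0.3065	0.3000	0.1843	0.1781	-47.5	0.3417	0.2055
case3	10	0.4442	0.1801	0.3000	0.1027	0.1492	-57.8	0.2402	0.1370
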