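PC	var_pct	pve	se
1	18.9	0.83	0.09
2	15.4	0.95	0.08
3	9.9	0.78	0.10
4	7.1	0.62	0.14
5	5.9	0.49	0.12
6	5.1	0.83	0.10
7	3.9	0.53	0.12
8	3.2	0.89	0.11
9	2.8	0.89	0.09
10	2.5	0.86	0.13
11	2.1	0.72	0.14
12	1.8	0.60	0.15
13	1.7	0.68	0.13
14	1.5	0.56	0.16
15	1.4	0.53	0.15
16	1.3	0.26	0.16
17	1.2	0.14	0.20
18	1.0	0.51	0.14
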