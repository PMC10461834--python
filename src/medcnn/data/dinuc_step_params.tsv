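property	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
Twist	35.1	31.5	31.9	29.3	37.3	32.9	36.1	31.9	36.3	33.6	32.9	31.5	37.8	36.3	37.3	35.1
Tilt	-1.4	-0.1	-1.7	0.0	0.5	-0.1	0.0	1.7	-1.5	0.0	0.1	0.1	0.0	1.5	-0.5	1.4
Roll	0.7	0.7	4.5	1.1	4.7	3.6	5.4	4.5	1.9	0.3	3.6	0.7	3.3	1.9	4.7	0.7
Shift	-0.03	0.13	0.09	0.0	0.09	0.05	0.0	-0.09	-0.28	0.0	-0.05	-0.13	0.0	0.28	-0.09	0.03
Slide	-0.08	-0.58	-0.25	-0.59	0.53	-0.22	0.41	-0.25	0.09	-0.38	-0.22	-0.58	0.05	0.09	0.53	-0.08
Rise	3.27	3.36	3.34	3.31	3.33	3.42	3.39	3.34	3.37	3.40	3.42	3.36	3.42	3.37	3.33	3.27
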