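location	wt_n	wt_p_small	wt_p_large	mt_n	mt_p_small	mt_p_large
COR	1013	0.34	0.66	875	0.34	0.66
INT	121	0.77	0.23	200	0.71	0.29
RIM	509	0.70	0.30	520	0.62	0.38
SUP	150	0.49	0.51	156	0.44	0.56
SUR	248	0.92	0.08	290	0.90	0.10
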