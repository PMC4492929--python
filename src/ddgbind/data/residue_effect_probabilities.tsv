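aa	wt_n	wt_p_small	wt_p_large	mt_n	mt_p_small	mt_p_large
A	88	0.58	0.42	923	0.64	0.36
C	7	0.86	0.14	45	0.58	0.42
D	112	0.49	0.51	68	0.49	0.51
E	194	0.53	0.47	68	0.47	0.53
F	44	0.61	0.39	88	0.64	0.36
G	96	0.27	0.73	59	0.31	0.69
H	40	0.53	0.48	46	0.57	0.43
I	52	0.58	0.42	52	0.44	0.56
K	201	0.65	0.35	80	0.43	0.58
L	133	0.34	0.66	63	0.43	0.57
M	25	0.76	0.24	50	0.52	0.48
N	158	0.68	0.32	56	0.50	0.50
P	99	0.70	0.30	42	0.19	0.81
Q	57	0.81	0.19	70	0.54	0.46
R	177	0.63	0.37	68	0.40	0.60
S	91	0.80	0.20	62	0.44	0.56
T	162	0.44	0.56	42	0.43	0.57
V	52	0.58	0.42	58	0.47	0.53
W	54	0.43	0.57	54	0.46	0.54
Y	199	0.30	0.70	47	0.51	0.49
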