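variant	disorder	tm_dsc	tm_dsc_secondary	t_half_cd210	t_half_cd220
wt	0.03	71.1	NA	73.8	72.4
cp211	0.31	66.2	NA	66.4	64.3
cp244	0.40	54.9	NA	54.5	60.4
cp256	0.66	NA	NA	57.6	55.6
cp269	0.23	65.5	NA	56.6	55.5
cp282	0.38	61.1	NA	63.4	62.7
cp297	0.69	51.0	45.1	59.2	59.8
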