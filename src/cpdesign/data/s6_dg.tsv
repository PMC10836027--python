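variant	study	dG_kcal_mol
P13-14	miller2002	4.1
P35-36	miller2002	5.4
WT	miller2002	8.5
P54-55	miller2002	9.1
P13-14	oliveberg-group	3.89
P13-14	oliveberg-group	4.29
P81-82	oliveberg-group	5.15
P33-34	oliveberg-group	5.76
P68-69	oliveberg-group	6.82
P68-69	oliveberg-group	6.91
WT	oliveberg-group	8.22
WT	oliveberg-group	8.97
P54-55	oliveberg-group	9.36
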