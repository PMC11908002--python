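population	n_pp	n_pm	n_mm
Barki	4	13	7
Rahmani	0	0	24
RahmanixBarki	1	3	20
Awassi	0	24	0
Ossimi	0	20	4
RomanovxRahmani	0	0	24
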