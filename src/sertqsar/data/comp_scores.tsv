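id	CompScore
A	1.521
A1	0.010
A2	0.805
A3	1.033
A4	-2.649
A5	1.070
A6	0.479
A7	-0.930
A8	0.730
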