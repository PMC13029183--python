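id	smiles	pic50
A	FC(c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)c1ccccc1)(F)F	7.8952
A1	Fc1ccccc1c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F	8.0215
A2	Fc1cccc(c1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F	7.9310
A3	Fc1ccc(cc1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F	8.1855
A4	CC(c1ccccc1c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F)C	8.0070
A5	CC(C)c1cccc(c1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F	7.6785
A6	CC(c1ccc(cc1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F)C	8.0295
A7	N#Cc1ccc(cc1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F	8.1943
A8	CN(c1ccc(cc1)c1cc(COCC2(CCNCC2)c2ccccc2)cc(c1)C(F)(F)F)C	8.4814
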