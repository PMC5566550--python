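compound,pair,experimental_Hz,qualifier,calculated_Hz
1,P-C2,2.7,,1.5
1,P-C4,4.4,,3.9
1,P-C2',9.2,,8.5
2,P-C3,2.0,<,1.5
2,P-C5,7.1,,6.1
2,P-C2',7.4,,6.7
3,P-C5,7.8,,6.9
3,P-C2',7.9,,7.2
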