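# curated allele attributes; floxed status cannot be read off the symbol
gene	designation	attribute
Zfp541	em1Osb	null
Lepr	tm1.1Chua	floxed
Mcl1	tm1Ywh	floxed
Hnf4a	tm1Sad	floxed
Pkd1	tm2Ggg	floxed
Mybl2	tm1.1Epr	floxed
Trp53	tm1Tyj	null
Kras	tm4Tyj	point_mutation
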