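allele_composition	category	annotation
Zfp541<em1Osb>/Zfp541<em1Osb>	I1	Zfp541 conventional knockout (global knockout)
Tg(Myh6-Acsl1)J3Jesc/0	I2	Overexpressing Acsl1 in cardiovascular system
Agrp<tm1(cre)Lowl>/Agrp<+> Lepr<tm1.1Chua>/Lepr<tm1.1Chua>	C1	Knockout Lepr specifically in neurons
Gt(ROSA)26Sor<tm1(cre/ERT2)Thl>/Gt(ROSA)26Sor<+> Mcl1<tm1Ywh>/Mcl1<tm1Ywh>	C2	Knockout Mcl1 ubiquitously in a tamoxifen-inducible manner.
Tg(Scgb1a1-rtTA)1Jaw/0 Tg(tetO-Aimp1)29872Mcla/0	C3	tetracycline/doxycycline treatment induced overexpression of Aimp1 in respiratory system.
Hnf4a<tm1Sad>/Hnf4a<tm1Sad> Six2<tm1(tTA,tetO-EGFP/cre)Amc>/Six2<+>	C5	Inactivating Hnf4a in renal & urinary system, especially in metanephric mesenchyme. Inactivation is marked by EGFP, tetracycline/doxycycline treatment restore the expression of Hnf4a.
Pkd1<tm2Ggg>/Pkd1<+> Tg(Pax8-rtTA2S*M2)1Koes/0 Tg(tetO-cre)1Jaw/0	C6	Inactivating Pkd1 heterozygously in the kidney. The inactivation is induced by tetracycline(or doxycycline) treatment.
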