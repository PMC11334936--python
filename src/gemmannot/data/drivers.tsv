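# promoter -> expression pattern (curated from public mouse-genome resources)
promoter	tissue_phrase	ubiquitous
Agrp	neurons	0
Myh6	cardiovascular system	0
Scgb1a1	respiratory system	0
Six2	renal & urinary system, especially in metanephric mesenchyme	0
Pax8	the kidney	0
Gt(ROSA)26Sor	ubiquitously	1
Mx1	interferon-responsive cells, including liver and hematopoietic cells	0
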