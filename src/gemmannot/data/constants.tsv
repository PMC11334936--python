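# documented molecular facts of the Cre-loxP system (not used in classification)
name	value
loxP_site_bp	34
cre_length_aa	343
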