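profile	token
Sigma70_r1_1	r1_1
Sigma70_r1_2	r1_2
Sigma70_ner	ner
Sigma70_r2	r2
Sigma70_r3	r3
Sigma70_r4	r4
Sigma70_r4_2	r4_2
Sigma70_ECF	ECF
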