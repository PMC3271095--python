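cohort	n_CC	n_CT	n_TT
mild_tbmn	30	11	3
severe_tbmn	45	13	1
mild_cfhr5	39	6	0
severe_cfhr5	21	12	0
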