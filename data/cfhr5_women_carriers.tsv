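group	carriers	total
mild_women	3	27
severe_women	3	6
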