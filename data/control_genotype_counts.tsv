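# healthy controls; counts reconstructed from rounded percentages (70/27/3 of 232),
# so the HWE p-value is checked for non-rejection only, not as an exact value
cohort	n_CC	n_CT	n_TT
controls	162	63	7
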