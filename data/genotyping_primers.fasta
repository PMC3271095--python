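>fwd_bsri engineered mismatch: penultimate base A (template T) completes a BsrI site with the T allele
CAAAGTGTAACAGATATCAGTGTCTCCCCGTGTCCTCTCCCAG
>rev
GCTTTGCTAATACCTTCTCCAGACTGTCCTCTGCTGCACTGA
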