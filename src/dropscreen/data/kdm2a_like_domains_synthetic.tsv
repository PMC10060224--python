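# Synthetic KDM2A-like domain fixture: plausible intervals for a 1162-aa
# JmjC-family histone demethylase; NOT curated annotations.
name	aa_start	aa_end
JmjC	148	316
CXXC	563	611
PHD	617	678
F-box	848	885
LRR	930	1120
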