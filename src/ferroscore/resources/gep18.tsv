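gene	weight
CCL5	1.0
CD27	1.0
CD274	1.0
CD276	1.0
CD8A	1.0
CMKLR1	1.0
CXCL9	1.0
CXCR6	1.0
HLA-DQA1	1.0
HLA-DRB1	1.0
HLA-E	1.0
IDO1	1.0
LAG3	1.0
NKG7	1.0
PDCD1LG2	1.0
PSMB10	1.0
STAT1	1.0
TIGIT	1.0
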