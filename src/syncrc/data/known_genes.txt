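APC
TP53
KRAS
BRAF
NRAS
PIK3CA
PTEN
SMAD4
TCF7L2
ACVR2A
FBXW7
MSH3
MLH1
ERBB2
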