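pathway	gene
ATM	ATM
ATM	CHEK2
p53	TP53
p53	ATM
p53	CHEK2
Wnt/b-catenin	APC
Wnt/b-catenin	CTNNB1
Wnt/b-catenin	TCF7L2
ERBB	ERBB2
ERBB	EGFR
PTEN	PTEN
PI3K/AKT	PIK3CA
PI3K/AKT	AKT1
PI3K/AKT	PTEN
ERK/MAPK	KRAS
ERK/MAPK	NRAS
ERK/MAPK	BRAF
TGF-beta	SMAD4
TGF-beta	TGFBR2
TGF-beta	ACVR2A
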