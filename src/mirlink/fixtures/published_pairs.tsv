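mirna	gene
hsa-miR-486-5p	ITGA5
hsa-miR-125a-5p	NIPAL4
hsa-miR-125a-5p	ALDH1A3
hsa-let-7e-5p	EDN1
hsa-let-7e-5p	HCN2
hsa-let-7e-5p	SMAD7
hsa-miR-135a-5p	ZNF385B
hsa-miR-135a-5p	BMPER
hsa-miR-140-3p	FKBP3
hsa-miR-140-3p	SKP1
hsa-miR-140-3p	NDUFA4
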