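mirna	direction
hsa-miR-135a-5p	up
hsa-miR-140-3p	up
hsa-miR-145-5p	up
hsa-miR-486-5p	down
hsa-miR-486-3p	down
hsa-miR-125a-5p	down
hsa-let-7e-5p	down
hsa-let-7d-3p	down
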