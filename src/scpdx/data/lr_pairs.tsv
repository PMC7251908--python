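ligand	receptor	annotation
CD274	PDCD1	immune_checkpoint
PDCD1LG2	PDCD1	immune_checkpoint
CD80	CTLA4	immune_checkpoint
CD86	CTLA4	immune_checkpoint
PVR	TIGIT	immune_checkpoint
FGL1	LAG3	immune_checkpoint
TGFB1	TGFBR2	stromal
CXCL12	CXCR4	stromal
MDK	LRP1	stromal
IGF1	IGF1R	stromal
CD47	SIRPA	myeloid
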