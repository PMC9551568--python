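apoptosis_up	upregulated apoptosis-pathway genes (signaling targets)	BCL2	BIRC3	CAPN2	CASP6	CASP7	CTSH	FADD	FOS	GADD45G	IL3RA	NFKBIA	PARP4	RELA	TNFRSF10A	TNFRSF10B	TNFRSF1A	TUBA1C
tnf_signaling_up	upregulated TNF-signaling-pathway genes (signaling targets)	BIRC3	CASP7	CEBPB	CREB3L2	FADD	FOS	IRF1	MAP2K3	MLKL	NFKBIA	RELA	TNFRSF1A
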