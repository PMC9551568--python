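tnf_receptors_up	upregulated TNF-family receptors (signaling sources)	TNFRSF10A	TNFRSF10B	TNFRSF1A
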