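code	amino_acid	provenance
DVATITAI	Ala	BIIRfg
DVTHSGSV	Glu	BIIRfg
DVSNVGSI	Asn	BIIRfg
DVQTVMAI	Ser	BIIRfg
DAQTIMAI	Thr	BIIRfg
DVSNVIGI	Gly	BIIRfg
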