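NOTCH_UP	NOTCH target genes expected higher in NOTCH-activated tumors	HES1	HES2	HES4	HES5	HEY1	HEY2	HEYL	NRARP	MYC	CDK6	CCND1	KIT	NOTCH1	NOTCH3	DTX1	DLL1	DLL3	JAG1	JAG2	LFNG	SOX9
NOTCH_DOWN	Genes expected lower in NOTCH-activated tumors	LXN	RAPGEF3	TMEM154	LGR6
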