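# Published worked example: GO terms extracted (EF >= 2, nf >= 5, p < 0.05)
# for male-offspring genes with differential expression accompanied by
# altered CpG-island methylation.  p-values below the reporting limit are
# printed as "<0.001".
category_id	term	enrichment_factor	p_value
GO:0005923	Bicellular tight junction	8.99	<0.001
GO:0015629	Actin cytoskeleton	5.07	0.003
GO:0003779	Actin binding	3.28	0.018
GO:0008285	Negative regulation of cell population proliferation	3.07	0.024
GO:0045893	Positive regulation of transcription, DNA-templated	2.71	0.014
GO:0007275	Multicellular organism development	2.63	0.001
GO:0003700	DNA-binding transcription factor activity	2.63	0.017
GO:0043565	Sequence-specific DNA binding	2.50	0.033
GO:0030054	Cell junction	2.42	0.012
GO:0006355	Regulation of transcription, DNA-templated	2.34	0.010
GO:0000981	DNA-binding transcription factor activity, RNA polymerase II-specific	2.14	0.038
GO:0045944	Positive regulation of transcription by RNA polymerase II	2.08	0.029
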