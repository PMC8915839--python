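# Published worked example: MeSH terms extracted (EF >= 2, nf >= 5, p < 0.05)
# for male-offspring genes with differential expression accompanied by
# altered CpG-island methylation.
category_id	term	enrichment_factor	p_value
D060850	LIM-Homeodomain Proteins	8.73	<0.001
D019070	Cell Lineage	6.21	<0.001
D051792	Basic Helix-Loop-Helix Transcription Factors	4.98	0.001
D015534	Trans-Activators	4.90	0.004
D013234	Stem Cells	4.83	0.002
D012097	Repressor Proteins	4.30	0.003
D018398	Homeodomain Proteins	4.19	<0.001
D009024	Morphogenesis	3.32	0.018
D018507	Gene Expression Regulation, Developmental	3.13	<0.001
D009419	Nerve Tissue Proteins	3.09	0.013
D017403	In Situ Hybridization	3.07	0.005
D004622	Embryo, Mammalian	3.01	0.003
D014157	Transcription Factors	2.76	0.009
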