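# Published worked example: probe-level records for the genes whose mRNA was
# downregulated (fold <= 0.67) with increased CpG-island methylation
# (fold >= 1.5) in male neonatal mouse brain after prenatal TiO2-NP exposure.
# expr_fold: mRNA fold change (exposed/sham); meth_fold: fold change of
# relative methylation (exposed/sham) at the probe's island position.
accession	symbol	locus	expr_fold	meth_fold
NM_001161855	4933416C03Rik	chr10:115551150-115551194	0.165	2.153
NM_008532	Epcam	chr17:88039798-88039842	0.013	1.729
NM_008192	Gucy2e	chr11:69049315-69049359	0.105	1.541
NR_027967	Hhatl	chr9:121698137-121698187	0.600	2.288
NM_213729	Inca1	chr11:70513486-70513530	0.196	1.704
NM_027397	Isl2	chr9:55394278-55394322	0.045	1.522
NM_001033250	Lemd1	chr1:134086976-134087020	0.188	1.840
NM_015743	Nr4a3	chr4:48060289-48060333	0.056	2.393
NM_008814	Pdx1	chr5:148081815-148081859	0.078	1.623
NM_009027	Rasgrf2	chr13:92901976-92902020	0.263	3.225
NM_001164704	Renbp	chrX:71167531-71167575	0.199	3.621
NM_001033415	Shisa3	chr5:67999755-67999799	0.306	1.502
NM_173429	Zfp775	chr6:48569751-48569795	0.664	1.528
NM_173429	Zfp775	chr6:48570111-48570155	0.664	1.549
NM_173429	Zfp775	chr6:48570207-48570251	0.664	2.012
NM_173429	Zfp775	chr6:48570342-48570386	0.664	2.204
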