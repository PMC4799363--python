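name	first_protein	second_protein	first_junction_residue	second_junction_residue	fusion_helix_sequence
3,305	Protein A	mbp3-16	266	13	QCAREAAREAAACD
3,306	mbp3-16	Protein A	133	217	QCAREAAAREAACN
3,307	Protein A	mbp3-16	263	13	NCAQEAAAREAACD
3,308	mbp3-16	Protein A	129	217	ACILQAAAREAACN
3,309	Protein A	mbp3-16	266	17	QCAREAAARDLGCK
3,310	mbp3-16	Protein A	133	219	QCAREAAAREANCE
3,311	mbp3-16	Protein A	132	227	LCKNKAQQAAFYCI
3,312	mbp3-16	Protein A	125	220	NCRLAAILAKNKCQ
3,313	Protein A	mbp3-16	259	18	ACKLNAAQALGRCL
3,315	Protein A	mbp3-16	260	18	ACLNAAQAALGRCL
4,254	Protein A	mbp3-16	260	21	KCLNDALGAKLLCA
4,256	Protein A	mbp3-16	260	21	KCLNDAQAAKLLCA
4,257	Protein A	mbp3-16	259	18	ACKLNAAQALGRCL
4,258	Protein A	mbp3-16	259	18	ACKLNAAQAAGRCL
4,260	Protein A	mbp3-16	261	22	KCNDAAARALLECA
4,261	Protein A	mbp3-16	261	21	KCNDAALGAKLLCA
4,262	Protein A	mbp3-16	261	21	KCNDAAAGAKLLCA
6,758	Protein A	Calmodulin	260	15	KCLNDAEQIAEFCE
6,759	Protein A	Calmodulin	260	16	KCLNDEQIAEFKCA
6,760	Protein A	Calmodulin	259	16	ACKLNAQIAEFKCA
6,761	Protein A	Calmodulin	260	10	KCLNDAQAAAEECI
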