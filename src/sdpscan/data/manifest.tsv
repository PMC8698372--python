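# file	label	description
rel_mut.tsv	rel_mut	Relative mutability of the 20 amino acids (Ala = 100)
pol_G.tsv	pol_G	Amino-acid polarity (Grantham)
hdf_KD.tsv	hdf_KD	Hydropathicity (Kyte & Doolittle)
hdf_Eisenb.tsv	hdf_Eisenb	Normalized consensus hydrophobicity (Eisenberg)
hdf_Cho.tsv	hdf_Cho	Hydrophobicity as proportion of 95% buried residues (Chothia)
flex.tsv	flex	Average flexibility index
coil.tsv	coil	Conformational parameter for coil (Deleage & Roux)
MW.tsv	MW	Molecular weight of each amino acid (Daltons)
bulkiness.tsv	bulkiness	Bulkiness (side-chain volume measure)
betap.tsv	betap	Conformational parameter for beta-sheet (Chou & Fasman)
alphap.tsv	alphap	Conformational parameter for alpha-helix (Deleage & Roux)
betatLp.tsv	betatLp	Normalized frequency for beta-turn (Levitt)
factor1.tsv	factor1	Atchley factor I: polarity / accessibility / hydrophobicity
factor2.tsv	factor2	Atchley factor II: propensity for secondary structure
factor3.tsv	factor3	Atchley factor III: molecular size / volume
factor4.tsv	factor4	Atchley factor IV: codon composition / relative amino-acid composition
factor5.tsv	factor5	Atchley factor V: electrostatic charge
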