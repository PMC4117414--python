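backbone	Backbone unit (N-CA-C-O)	backbone__ANY.pdb
peptide_bond	Peptide bond (CA-C-O + N-CA)	peptide_bond__ANY.pdb
hydroxyl	Hydroxyl	hydroxyl__SER.pdb,hydroxyl__THR.pdb,hydroxyl__TYR.pdb
carboxylate	Carboxylate	carboxylate__ASP.pdb,carboxylate__GLU.pdb
carboxamide	Carboxamide	carboxamide__ASN.pdb,carboxamide__GLN.pdb
guanidinium	Guanidinium	guanidinium__ARG.pdb
imidazole	Imidazole ring	imidazole__HIS.pdb
phenyl_ring	Phenyl ring	phenyl_ring__PHE.pdb
phe_linker	Phenylalanine linker (CA-CB-CG)	phe_linker__PHE.pdb
tyr_ring	Tyrosine ring	tyr_ring__TYR.pdb
indole	Indole ring	indole__TRP.pdb
thiol	Thiol	thiol__CYS.pdb
thioether	Thioether	thioether__MET.pdb
met_linker	Methionine linker (CA-CB-CG)	met_linker__MET.pdb
ammonium	Ammonium	ammonium__LYS.pdb
lys_linker	Lysine linker (CA-CB-CG-CD)	lys_linker__LYS.pdb
arg_linker	Arginine linker (CA-CB-CG-CD)	arg_linker__ARG.pdb
ala_methyl	Alanine methyl	ala_methyl__ALA.pdb
val_branch	Valine branch	val_branch__VAL.pdb
ile_chain	Isoleucine side chain	ile_chain__ILE.pdb
leu_branch	Leucine branch	leu_branch__LEU.pdb
thr_branch	Threonine branch	thr_branch__THR.pdb
ser_linker	Serine linker	ser_linker__SER.pdb
pro_ring	Pyrrolidine ring	pro_ring__PRO.pdb
asp_linker	Aspartate linker (CA-CB)	asp_linker__ASP.pdb
glu_linker	Glutamate linker (CA-CB-CG)	glu_linker__GLU.pdb
asn_linker	Asparagine linker (CA-CB)	asn_linker__ASN.pdb
gln_linker	Glutamine linker (CA-CB-CG)	gln_linker__GLN.pdb
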