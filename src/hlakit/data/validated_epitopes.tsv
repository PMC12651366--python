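# IEDB-validated neoepitopes from recurrent cancer driver mutations, used for
# cross-referencing predicted catalogs. hla_restriction is the presenting
# allele reported for the epitope; assay_type the positive assay category.
gene	mutation	mt_sequence	wt_sequence	hla_restriction	assay_type
EGFR	A289V	YSFGVTCV	YSFGATCV	HLA-C*02:02	T cell assay
KRAS	G12D	GADGVGKSAL	GAGGVGKSAL	HLA-C*05:01	MHC ligand assay; T cell assay
KRAS	G12D	VVVGADGVGK	VVVGAGGVGK	HLA-C*03:03	MHC ligand assay; T cell assay
NRAS	Q61K	ILDTAGKEEY	ILDTAGQEEY	HLA-A*01:01	MHC ligand assay; T cell assay
TP53	R248W	MNWRPILTI	MNRRPILTI	HLA-C*06:02	MHC ligand assay
TP53	R273C	EVCVCACPGR	EVRVCACPGR	HLA-A*68:01	MHC ligand assay
TP53	R248Q	SSCMGGMNQR	SSCMGGMNRR	HLA-A*11:01	MHC ligand assay
TP53	R175H	EVVRHCPHHER	EVVRRCPHHER	HLA-A*68:01	MHC ligand assay
TP53	C135F	YSPALNKMFF	YSPALNKMFC	HLA-B*15:17	MHC ligand assay
TP53	Y220C	VVPCEPPEV	VVPYEPPEV	HLA-C*16:01	MHC ligand assay; T cell assay
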