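# Curated antigen-presentation gene panels (best-effort reconstruction of the
# functional modules commonly used in immuno-oncology expression analyses;
# editable). Columns: pathway, gene.
pathway	gene
app_core	TAP1
app_core	TAP2
app_core	TAPBP
app_core	ERAP1
app_core	ERAP2
app_core	CALR
app_core	CANX
app_core	PDIA3
app_core	NLRC5
app_hsp	HSPA1A
app_hsp	HSPA1B
app_hsp	HSPA4
app_hsp	HSPA5
app_hsp	HSPA8
app_hsp	HSP90AA1
app_hsp	HSP90AB1
app_hsp	HSP90B1
hla_class_I	HLA-A
hla_class_I	HLA-B
hla_class_I	HLA-C
hla_class_I	B2M
hla_class_II	HLA-DRA
hla_class_II	HLA-DRB1
hla_class_II	HLA-DQA1
hla_class_II	HLA-DQB1
hla_class_II	HLA-DPA1
hla_class_II	HLA-DPB1
hla_class_II	HLA-DMA
hla_class_II	HLA-DMB
hla_class_II	CD74
proteasome	PSMB5
proteasome	PSMB6
proteasome	PSMB7
proteasome	PSMB8
proteasome	PSMB9
proteasome	PSMB10
proteasome	PSME1
proteasome	PSME2
t_cell_markers	CD3D
t_cell_markers	CD3E
t_cell_markers	CD3G
t_cell_markers	CD4
t_cell_markers	CD8A
t_cell_markers	CD8B
t_cell_markers	GZMB
t_cell_markers	PRF1
immune_tf	CIITA
immune_tf	CREB1
immune_tf	ICAM1
immune_tf	IRF1
immune_tf	STAT1
immune_tf	NFKB1
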