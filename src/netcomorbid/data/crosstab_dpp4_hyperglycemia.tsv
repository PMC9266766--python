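# Association grid: hyperglycemia-network genes shared with the DPP4 interactor neighborhood.
# Columns: target-relation category, condition-relation category, comma-joined gene symbols.
upregulated_by_target	upregulated_by_condition	CD36,CD8A,CRP,IL6,MMP2,SPP1
upregulated_by_target	downregulated_by_condition	CD44,HIF1A,VEGFA
upregulated_by_target	anti_condition_activity	PPARG
upregulated_by_target	other	PLAT
downregulated_by_target	upregulated_by_condition	CCL11,FGF2,HMGB1,MMP9,NPY,THBS1,VIP
downregulated_by_target	downregulated_by_condition	PPY
downregulated_by_target	pro_condition_activity	CREB1,EGR1,GCG,GIP
downregulated_by_target	anti_condition_activity	ADIPOQ,EPO,GLP1R,INS,SERPINF1
downregulated_by_target	other	CXCL12,GHRH,NPHS1
upregulates_target	upregulated_by_condition	CCL11,EGFR,IFNG,TNF
upregulates_target	anti_condition_activity	INS
upregulates_target	other	IL2,IL13
downregulates_target	upregulated_by_condition	NPY,TLR4
downregulates_target	anti_condition_activity	MYC
downregulates_target	other	PTH,TFPI
other	upregulated_by_condition	CXCR4,FN1
other	downregulated_by_condition	CDH1
other	pro_condition_activity	GCG,NOS2
other	anti_condition_activity	CAV1,KL
other	other	HNF1A,LGALS3
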