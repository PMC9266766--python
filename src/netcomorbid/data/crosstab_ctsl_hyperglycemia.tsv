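# Association grid: hyperglycemia-network genes shared with the cathepsin L (CTSL) interactor neighborhood.
# Columns: target-relation category, condition-relation category, comma-joined gene symbols.
upregulated_by_target	upregulated_by_condition	BCL2,CXCL8,HPSE
upregulated_by_target	downregulated_by_condition	BCL2
downregulated_by_target	upregulated_by_condition	CDKN1A,LEPR
downregulated_by_target	downregulated_by_condition	CDH1
downregulated_by_target	pro_condition_activity	IGFBP3
downregulated_by_target	other	LEPR,TF
upregulates_target	upregulated_by_condition	FGF2,FOXO1,HPSE,IL6,JUN,MAPK1
upregulates_target	anti_condition_activity	INS,MYC
upregulates_target	other	FOS
downregulates_target	upregulated_by_condition	CDKN1A,TGFB1
other	upregulated_by_condition	CCL2,F3,TP53
other	downregulated_by_condition	PLAU
other	other	POMC
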