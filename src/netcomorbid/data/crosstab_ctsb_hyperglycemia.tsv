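# Association grid: hyperglycemia-network genes shared with the cathepsin B (CTSB) interactor neighborhood.
# Columns: target-relation category, condition-relation category, comma-joined gene symbols.
upregulated_by_target	upregulated_by_condition	BAX,BCL2,BDNF,CASP1,CASP3,CASP8,CCL2,CXCL8,DCX,IL18,MMP9,MTOR,NLRP3,PRL,PTEN
upregulated_by_target	downregulated_by_condition	BCL2,CCK,VEGFA
upregulated_by_target	pro_condition_activity	PRL
upregulated_by_target	anti_condition_activity	IL4,IL18,MTOR
upregulated_by_target	other	APOE,HSPG2
downregulated_by_target	upregulated_by_condition	APP,FN1
downregulated_by_target	downregulated_by_condition	BGLAP,SIRT1
downregulated_by_target	pro_condition_activity	CDKN1B
downregulated_by_target	anti_condition_activity	SIRT1
upregulates_target	upregulated_by_condition	CASP8,CXCL8,IL6,PRL,SP1,STAT3,TLR4,TNF
upregulates_target	downregulated_by_condition	CCK,NTN1
upregulates_target	pro_condition_activity	PRL
upregulates_target	anti_condition_activity	SMPD1,STAT3
upregulates_target	other	CXCL12,SNCA,SP1
downregulates_target	upregulated_by_condition	TGFB1
downregulates_target	downregulated_by_condition	VEGFA
downregulates_target	other	IL10
other	upregulated_by_condition	ANXA2,EGFR,HMGB1,MKI67,TP53
other	downregulated_by_condition	APOA1,KDR,PLAU
other	pro_condition_activity	IL1B
other	anti_condition_activity	CAV1,HGF
other	other	FOXO3
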