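# Association grid: hyperglycemia-network genes shared with the ACE2 interactor neighborhood.
# Columns: target-relation category, condition-relation category, comma-joined gene symbols.
upregulated_by_target	upregulated_by_condition	BCL2,CCND1,MMP2,NOS1,NOS3,SOD1,UCP2
upregulated_by_target	downregulated_by_condition	BCL2,CDH1,NOS3
upregulated_by_target	pro_condition_activity	IL1B,NOS2
upregulated_by_target	other	NPHS1,SIRT6
downregulated_by_target	upregulated_by_condition	ANGPT2,CCL2,CCN2,HMGB1,ICAM1,MIR21,MMP9,STAT3,VCAM1
downregulated_by_target	downregulated_by_condition	VEGFA
downregulated_by_target	pro_condition_activity	AGTR1
downregulated_by_target	anti_condition_activity	STAT3
downregulated_by_target	other	ACE,ICAM1
upregulates_target	upregulated_by_condition	HMGB1
upregulates_target	anti_condition_activity	INS
downregulates_target	upregulated_by_condition	EDN1
downregulates_target	downregulated_by_condition	SIRT1
downregulates_target	pro_condition_activity	AGTR1
downregulates_target	anti_condition_activity	INS,SIRT1
downregulates_target	other	ACE,ALB,APOE
other	upregulated_by_condition	AGT
other	downregulated_by_condition	CAT,IRS1
other	pro_condition_activity	GCG
other	other	CALM1
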