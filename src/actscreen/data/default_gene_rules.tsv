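gene_symbol	disease	category	inheritance	actionable_classes	named_variant	notes
BRCA1	hereditary breast-ovarian cancer	cancer	AD	all_P_LP
BRCA2	hereditary breast-ovarian cancer	cancer	AD	all_P_LP
MSH2	Lynch syndrome	cancer	AD	all_P_LP
MSH6	Lynch syndrome	cancer	AD	all_P_LP
PMS2	Lynch syndrome	cancer	AD	all_P_LP
APC	familial adenomatous polyposis	cancer	AD	all_P_LP
RET	multiple endocrine neoplasia type 2	cancer	AD	all_P_LP
MUTYH	MYH-associated polyposis	cancer	AR	all_P_LP		two variants must be present
TTR	hereditary transthyretin amyloidosis	metabolic	AD	all_P_LP
ATP7B	Wilson disease	metabolic	AR	all_P_LP		two variants must be present
BTD	biotinidase deficiency	metabolic	AR	all_P_LP		two variants must be present
GAA	Pompe disease	metabolic	AR	all_P_LP		two variants must be present
HFE	hereditary hemochromatosis	metabolic	AR	named_variant_hom_only	6:26092913:G:A	p.Cys282Tyr homozygotes only
KCNH2	long QT syndrome	cardiovascular	AD	all_P_LP
SCN5A	Brugada / long QT syndrome	cardiovascular	AD	all_P_LP
TTN	dilated cardiomyopathy	cardiovascular	AD	LoF_only		truncating variants only
COL3A1	vascular Ehlers-Danlos syndrome	cardiovascular	AD	all_P_LP
DES	desmin-related cardiomyopathy	cardiovascular	AD	all_P_LP
LDLR	familial hypercholesterolemia	cardiovascular	AD	all_P_LP
APOB	familial hypercholesterolemia	cardiovascular	AD	all_P_LP
PCSK9	familial hypercholesterolemia	cardiovascular	AD	all_P_LP
CASQ2	catecholaminergic polymorphic ventricular tachycardia	cardiovascular	AR	all_P_LP		two variants must be present
RPE65	RPE65-related retinopathy	other	AR	all_P_LP		two variants must be present
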