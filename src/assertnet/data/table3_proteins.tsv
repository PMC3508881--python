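concept_id	type	preferred_label	synonym
SERPINA3	PROTEIN_OR_MRNA	SERPINA3	Alpha 1-antichymotrypsin
SERPINA3	PROTEIN_OR_MRNA	SERPINA3	serpin peptidase inhibitor clade A
SERPINA3	PROTEIN_OR_MRNA	SERPINA3	AACT
SERPINA3	PROTEIN_OR_MRNA	SERPINA3	ACT
APP	PROTEIN_OR_MRNA	APP	Amyloid beta A4 precursor protein
APP	PROTEIN_OR_MRNA	APP	amyloid precursor protein
APP	PROTEIN_OR_MRNA	APP	ABETA
APP	PROTEIN_OR_MRNA	APP	AD1
APOD	PROTEIN_OR_MRNA	APOD	Apolipoprotein D
apoE	PROTEIN_OR_MRNA	apoE	Apolipoprotein E
apoE	PROTEIN_OR_MRNA	apoE	AD2
BCL2	PROTEIN_OR_MRNA	BCL2	B-cell leukemia lymphoma 2
BCL2	PROTEIN_OR_MRNA	BCL2	B-cell lymphoma 2
BACE1	PROTEIN_OR_MRNA	BACE1	Beta-site APP-Cleaving Enzyme 1
BACE1	PROTEIN_OR_MRNA	BACE1	BACE-1
BACE1	PROTEIN_OR_MRNA	BACE1	beta-secretase 1
BCHE	PROTEIN_OR_MRNA	BCHE	Butyrylcholinesterase
CRP	PROTEIN_OR_MRNA	CRP	C-reactive protein
CHAT	PROTEIN_OR_MRNA	CHAT	Choline Acetyltransferase
CHAT	PROTEIN_OR_MRNA	CHAT	CHOACTase
CHAT	PROTEIN_OR_MRNA	CHAT	ChAt
CLU	PROTEIN_OR_MRNA	CLU	Clusterin
CLU	PROTEIN_OR_MRNA	CLU	APOJ
CLU	PROTEIN_OR_MRNA	CLU	Apolipoprotein J
C1QB	PROTEIN_OR_MRNA	C1QB	Complement component 1 q subcomponent beta polypeptide
ESR1	PROTEIN_OR_MRNA	ESR1	Estrogen Receptor 1
ESR1	PROTEIN_OR_MRNA	ESR1	estrogen receptor alpha
GFAP	PROTEIN_OR_MRNA	GFAP	Glial fibrillary acidic protein
HSPA5	PROTEIN_OR_MRNA	HSPA5	Heat shock 70kD protein 5
HSPA5	PROTEIN_OR_MRNA	HSPA5	glucose-regulated protein 78
IL1B	PROTEIN_OR_MRNA	IL1B	Interleukin 1 beta
IL1B	PROTEIN_OR_MRNA	IL1B	IL-1beta
IL1B	PROTEIN_OR_MRNA	IL1B	IL-1β
IL6	PROTEIN_OR_MRNA	IL6	Interleukin 6
IL6	PROTEIN_OR_MRNA	IL6	IFNB2
IL6	PROTEIN_OR_MRNA	IL6	Interferon beta-2
MMP9	PROTEIN_OR_MRNA	MMP9	Matrix Metallopeptidase 9
MMP9	PROTEIN_OR_MRNA	MMP9	CLG4B
MMP9	PROTEIN_OR_MRNA	MMP9	92 kDa gelatinase
NGF	PROTEIN_OR_MRNA	NGF	Nerve Growth Factor
NGF	PROTEIN_OR_MRNA	NGF	NGFB
NOS2	PROTEIN_OR_MRNA	NOS2	Nitric Oxide Synthase 2A
NOS2	PROTEIN_OR_MRNA	NOS2	NOS2A
NOS2	PROTEIN_OR_MRNA	NOS2	INOS
NOS2	PROTEIN_OR_MRNA	NOS2	inducible nitric oxide synthase
PAWR	PROTEIN_OR_MRNA	PAWR	PRKC apoptosis WT1 regulator
PAWR	PROTEIN_OR_MRNA	PAWR	PAR4
PTGS2	PROTEIN_OR_MRNA	PTGS2	Prostaglandin-Endoperoxide Synthase 2
PTGS2	PROTEIN_OR_MRNA	PTGS2	PGHS2
PTGS2	PROTEIN_OR_MRNA	PTGS2	COX2
PTGS2	PROTEIN_OR_MRNA	PTGS2	Cyclooxygenase 2
TGFB1	PROTEIN_OR_MRNA	TGFB1	Transforming Growth Factor Beta 1
TGFB1	PROTEIN_OR_MRNA	TGFB1	TGF-beta 1
TTR	PROTEIN_OR_MRNA	TTR	Transthyretin
TNF	PROTEIN_OR_MRNA	TNF	Tumor Necrosis Factor
TNF	PROTEIN_OR_MRNA	TNF	TNFA
TNF	PROTEIN_OR_MRNA	TNF	TNF-alpha
TNF	PROTEIN_OR_MRNA	TNF	TNF-α
PLAUR	PROTEIN_OR_MRNA	PLAUR	Urokinase Plasminogen Activator Receptor
PLAUR	PROTEIN_OR_MRNA	PLAUR	uPAR
PLAUR	PROTEIN_OR_MRNA	PLAUR	CD87
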