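# Default riboswitch class -> family map (50 covariance-model classes, 27
# ligand-defined families). The c-di-GMP and Cobalamin memberships are fixed
# by the screen's design; remaining assignments group classes that sense the
# same ligand. Edit freely: two tab-separated columns, class then family.
c-di-GMP-I	c-di-GMP
c-di-GMP-II	c-di-GMP
c-di-GMP-I-GGC	c-di-GMP
c-di-GMP-II-GAG	c-di-GMP
c-di-GMP-I-UAU	c-di-GMP
c-di-GMP-II-GCG	c-di-GMP
Cobalamin	Cobalamin
AdoCbl	Cobalamin
AdoCbl-variant	Cobalamin
ykoK	ykoK / M-box
MOCO_RNA_motif	MOCO
AAC_AAD	AAC_AAD
glnA	glnA
nhaA-I	nhaA-I
sul1	sul1
Mg_sensor	Mg_sensor
Glycine	Glycine
DUF1646	DUF1646
raiA	raiA
ydaO-yuaA	ydaO-yuaA
FMN	FMN
ykkC	ykkC / Guanidine
mini-ykkC	ykkC / Guanidine
ykkC-III	ykkC / Guanidine
Guanidine-IV	ykkC / Guanidine
crcB	crcB / Fluoride
pfl	pfl / ZMP-ZTP
TPP	TPP
Purine	Purine
2dG-I	Purine
2dG-II	Purine
PreQ1	PreQ1
PreQ1-II	PreQ1
PreQ1-III	PreQ1
glmS	glmS
Lysine	Lysine
SAM	SAM
SAM-IV	SAM
SAM-I-IV-variant	SAM
SAM-II_long_loops	SAM
SAM-SAH	SAM
SMK_box_riboswitch	SAM
SAM-VI	SAM
SAM_alpha	SAM
yybP-ykoY	yybP-ykoY
THF	THF
THF-2	THF
NiCo	NiCo
NiCo-AnGGAG	NiCo
T-box	T-box
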