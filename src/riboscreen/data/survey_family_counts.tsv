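# Sense/antisense absolute frequencies of the 27 riboswitch families from a
# genome-scale screen of 5,418 representative prokaryotic genomes (one genome
# per species). Columns: family, sense_count, antisense_count.
family	sense	antisense
c-di-GMP	2554	152
Cobalamin	10769	190
ykoK / M-box	828	27
MOCO	834	24
AAC_AAD	97	3
glnA	97	2
nhaA-I	180	2
sul1	195	2
Mg_sensor	104	1
Glycine	3153	32
DUF1646	125	1
raiA	127	1
ydaO-yuaA	2799	27
FMN	3472	32
ykkC / Guanidine	2526	20
crcB / Fluoride	1446	9
pfl / ZMP-ZTP	1001	5
TPP	9766	83
Purine	2289	13
PreQ1	771	2
glmS	635	1
Lysine	1974	8
SAM	8039	56
yybP-ykoY	1907	5
THF	290	0
NiCo	100	0
T-box	15851	107
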