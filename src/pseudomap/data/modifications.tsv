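code	name	modomics_short	parents	formula	pyrimidine_derived	guanosine_derived	ce_reactive	blocks_cleavage	o18_eligible	mrm_product_rule
A	adenosine	A	A	C10H12N5O6P	0	0	0	0	0
G	guanosine	G	G	C10H12N5O7P	0	1	0	0	0
C	cytidine	C	C	C9H12N3O7P	1	0	0	0	0
U	uridine	U	U	C9H11N2O8P	1	0	0	0	1
Y	pseudouridine	Y	CU	C9H11N2O8P	1	0	1	0	1	loss:H4O2
D	dihydrouridine	D	U	C9H13N2O8P	1	0	0	0	0
m5U	5-methyluridine	5MU	U	C10H13N2O8P	1	0	0	0	0
Q	queuosine	Q	G	C17H22N5O9P	0	1	0	0	0
ms2io6A	2-methylthio-N6-(cis-hydroxyisopentenyl)adenosine	MS2IO6A	A	C16H22N5O7PS	0	0	0	0	0
I	inosine	I	AG	C10H11N4O7P	0	1	0	0	0
Am	2'-O-methyladenosine	AM	A	C11H14N5O6P	0	0	0	1	0	loss:C6H10O4
Gm	2'-O-methylguanosine	GM	G	C11H14N5O7P	0	1	0	1	0	loss:C6H10O4
Cm	2'-O-methylcytidine	CM	C	C10H14N3O7P	1	0	0	1	0	loss:C6H10O4
Um	2'-O-methyluridine	UM	U	C10H13N2O8P	1	0	0	1	0	loss:C6H10O4
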