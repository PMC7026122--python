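# RNA modification mass-shift registry (curated MODOMICS-derived subset).
# columns: search_code	name	shift_formula	placement	target_bases	isobaric_set
m5C	5-methylcytidine	CH2	base	C	m5C,m3C,m4C
Um	2'-O-methyluridine	CH2	sugar	U	Um
mA	adenosine monomethylation (base only)	CH2	base	A	m1A,m6A
mA?	adenosine monomethylation	CH2	either	A	m1A,m6A,Am
mC?	cytidine monomethylation	CH2	either	C	m3C,m4C,m5C,Cm
mG?	guanosine monomethylation	CH2	either	G	m1G,m2G,m7G,Gm
mU?	uridine or pseudouridine monomethylation	CH2	either	U	m3U,m5U,Um,m1Y,m3Y
m6,6A	N6,N6-dimethyladenosine	C2H4	base	A	m6,6A
m2,2G	N2,N2-dimethylguanosine	C2H4	base	G	m2,2G
D	dihydrouridine	H2	base	U	D
t6A	N6-threonylcarbamoyladenosine	C5H7NO4	base	A	t6A
ms2t6A	2-methylthio-N6-threonylcarbamoyladenosine	C6H9NO4S	base	A	ms2t6A
i6A	N6-isopentenyladenosine	C5H8	base	A	i6A
I	inosine	H-1N-1O1	base	A	I
m1I	1-methylinosine	CH1N-1O1	base	A	m1I
ac4C	N4-acetylcytidine	C2H2O	base	C	ac4C
ac4C/f5Cm?	N4-acetylcytidine or 5-formyl-2'-O-methylcytidine	C2H2O	either	C	ac4C,f5Cm
acp3U	3-(3-amino-3-carboxypropyl)uridine	C4H7NO2	base	U	acp3U,acp3Y
mcm5U	5-methoxycarbonylmethyluridine	C3H4O2	base	U	mcm5U
mcm5s2U	5-methoxycarbonylmethyl-2-thiouridine	C3H4OS	base	U	mcm5s2U
mcm5Um	5-methoxycarbonylmethyl-2'-O-methyluridine	C4H6O2	base	U	mcm5Um
cm5U	5-carboxymethyluridine	C2H2O2	base	U	cm5U
mchm5U	5-(carboxyhydroxymethyl)uridine methyl ester	C3H4O3	base	U	mchm5U
hm5C	5-hydroxymethylcytidine	CH2O	base	C	hm5C
hm5Cm	2'-O-methyl-5-hydroxymethylcytidine	C2H4O	base	C	hm5Cm
Q	queuosine	C7H10O2	base	G	Q
galQ/manQ	galactosyl- or mannosyl-queuosine	C13H20O7	base	G	galQ,manQ
yW	wybutosine	C11H15NO4	base	G	yW
m1acp3Y	1-methyl-3-(3-amino-3-carboxypropyl)pseudouridine	C5H9NO2	base	U	m1acp3Y
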