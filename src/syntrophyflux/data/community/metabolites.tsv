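met_id	compartment	formula	charge	name
ac[e]	e	C2H3O2	-1	acetate
for[e]	e	CHO2	-1	formate
co2[e]	e	CO2	0	carbon dioxide
ch4[e]	e	CH4	0	methane
h2[e]	e	H2	0	dihydrogen
h2o[e]	e	H2O	0	water
h[e]	e	H	1	proton
atp[saob]	saob	C10H12N5O13P3	-4	ATP
adp[saob]	saob	C10H12N5O10P2	-3	ADP
pi[saob]	saob	HPO4	-2	phosphate
h[saob]	saob	H	1	proton
h2o[saob]	saob	H2O	0	water
co2[saob]	saob	CO2	0	carbon dioxide
h2[saob]	saob	H2	0	dihydrogen
imf[saob]	saob		0	ion-motive force (ATP-equivalent units)
ac[saob]	saob	C2H3O2	-1	acetate
for[saob]	saob	CHO2	-1	formate
coa[saob]	saob	C21H32N7O16P3S	-4	coenzyme A
accoa[saob]	saob	C23H34N7O17P3S	-4	acetyl-CoA
actp[saob]	saob	C2H3O5P	-2	acetyl phosphate
thf[saob]	saob	Th	0	tetrahydrofolate
m5thf[saob]	saob	CH2Th	0	5-methyl-THF
mlthf[saob]	saob	CTh	0	5,10-methylene-THF
f10thf[saob]	saob	COTh	0	10-formyl-THF
nad[saob]	saob	Nd	-1	NAD+
nadh[saob]	saob	NdH	-2	NADH
fdox[saob]	saob	Fd	0	oxidized ferredoxin
fdred[saob]	saob	Fd	-2	reduced ferredoxin
mq[saob]	saob	Mq	0	menaquinone
mqh2[saob]	saob	MqH2	0	menaquinol
atp[m1]	m1	C10H12N5O13P3	-4	ATP
adp[m1]	m1	C10H12N5O10P2	-3	ADP
pi[m1]	m1	HPO4	-2	phosphate
h[m1]	m1	H	1	proton
h2o[m1]	m1	H2O	0	water
co2[m1]	m1	CO2	0	carbon dioxide
h2[m1]	m1	H2	0	dihydrogen
imf[m1]	m1		0	ion-motive force (ATP-equivalent units)
ch4[m1]	m1	CH4	0	methane
fdox[m1]	m1	Fd	0	oxidized ferredoxin
fdred[m1]	m1	Fd	-2	reduced ferredoxin
fo[m1]	m1	Fo	0	oxidized F420
foh2[m1]	m1	FoH2	0	reduced F420
mh[m1]	m1	Mh	0	H4MPT
m3mh[m1]	m1	CH2Mh	0	methyl-H4MPT
com[m1]	m1	C2H5O3S2	-1	coenzyme M (thiol)
cob[m1]	m1	C11H22NO7PS	-2	coenzyme B (thiol)
hsds[m1]	m1	C13H25NO10PS3	-3	CoM-S-S-CoB heterodisulfide
mcom[m1]	m1	C3H7O3S2	-1	methyl-CoM
atp[m2]	m2	C10H12N5O13P3	-4	ATP
adp[m2]	m2	C10H12N5O10P2	-3	ADP
pi[m2]	m2	HPO4	-2	phosphate
h[m2]	m2	H	1	proton
h2o[m2]	m2	H2O	0	water
co2[m2]	m2	CO2	0	carbon dioxide
h2[m2]	m2	H2	0	dihydrogen
imf[m2]	m2		0	ion-motive force (ATP-equivalent units)
ch4[m2]	m2	CH4	0	methane
fdox[m2]	m2	Fd	0	oxidized ferredoxin
fdred[m2]	m2	Fd	-2	reduced ferredoxin
fo[m2]	m2	Fo	0	oxidized F420
foh2[m2]	m2	FoH2	0	reduced F420
mh[m2]	m2	Mh	0	H4MPT
m3mh[m2]	m2	CH2Mh	0	methyl-H4MPT
com[m2]	m2	C2H5O3S2	-1	coenzyme M (thiol)
cob[m2]	m2	C11H22NO7PS	-2	coenzyme B (thiol)
hsds[m2]	m2	C13H25NO10PS3	-3	CoM-S-S-CoB heterodisulfide
mcom[m2]	m2	C3H7O3S2	-1	methyl-CoM
for[m2]	m2	CHO2	-1	formate
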