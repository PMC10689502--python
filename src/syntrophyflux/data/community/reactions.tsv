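rxn_id	guild	equation	lb	ub	atp_coeff	name
ACK	saob	1 ac[saob] + 1 atp[saob] -> 1 actp[saob] + 1 adp[saob]	0.0	1000.0	-1.0	acetate kinase
PTA	saob	1 actp[saob] + 1 coa[saob] -> 1 accoa[saob] + 1 pi[saob]	0.0	1000.0	0.0	phosphotransacetylase
CODH_ACS	saob	1 accoa[saob] + 1 thf[saob] + 1 h2o[saob] + 1 fdox[saob] -> 1 m5thf[saob] + 1 co2[saob] + 1 coa[saob] + 1 fdred[saob] + 2 h[saob]	0.0	1000.0	0.0	CO dehydrogenase / acetyl-CoA synthase (oxidative)
METFV	saob	1 m5thf[saob] + 1 mq[saob] -> 1 mlthf[saob] + 1 mqh2[saob]	0.0	1000.0	0.0	methylene-THF reductase (reverse, menaquinone-coupled)
MTHFD	saob	1 mlthf[saob] + 1 nad[saob] + 1 h2o[saob] -> 1 f10thf[saob] + 1 nadh[saob] + 1 h[saob]	0.0	1000.0	0.0	methylene-THF dehydrogenase / cyclohydrolase (oxidative)
FHS	saob	1 f10thf[saob] + 1 adp[saob] + 1 pi[saob] -> 1 for[saob] + 1 thf[saob] + 1 atp[saob]	0.0	1000.0	1.0	formate-THF ligase (oxidative)
FDH_NUO	saob	2 for[saob] + 1 nad[saob] + 1 fdox[saob] -> 2 co2[saob] + 1 nadh[saob] + 1 fdred[saob] + 1 h[saob]	0.0	1000.0	0.0	electron-confurcating FdhA-NuoEF
HYD3B	saob	1 nadh[saob] + 1 h[saob] -> 1 h2[saob] + 1 nad[saob]	0.0	1000.0	0.0	NADH-dependent Group 3b [NiFe]-hydrogenase
HYDABC	saob	1 fdred[saob] + 1 nadh[saob] + 3 h[saob] -> 2 h2[saob] + 1 fdox[saob] + 1 nad[saob]	0.0	1000.0	0.0	electron-bifurcating [FeFe]-HydABC
ECH	saob	1 fdred[saob] + 2 h[saob] -> 1 h2[saob] + 1 fdox[saob] + 0.5664057631 imf[saob]	0.0	1000.0	0.0	ion-pumping Ech hydrogenase
HYS	saob	1 mqh2[saob] + 0.6085812474 imf[saob] -> 1 h2[saob] + 1 mq[saob]	0.0	1000.0	0.0	periplasmic Hys-CytB hydrogenase (reverse electron transport)
FDH_CYTB	saob	1 mqh2[saob] + 1 co2[saob] + 0.8917841289 imf[saob] -> 1 for[e] + 1 mq[saob] + 1 h[saob]	0.0	1000.0	0.0	membrane Fdh-CytB (extracellular formate synthesis)
ATPS_saob	saob	1 adp[saob] + 1 pi[saob] + 1 h[saob] + 1 imf[saob] -> 1 atp[saob] + 1 h2o[saob]	0.0	1000.0	1.0	ATP synthase
ATPM_saob	saob	1 atp[saob] + 1 h2o[saob] -> 1 adp[saob] + 1 pi[saob] + 1 h[saob]	0.0	1000.0	-1.0	ATP yield sink
LEAK_saob	saob	1 imf[saob] -> 	0.0	1000.0	0.0	ion leak
ACt	saob	1 ac[e] -> 1 ac[saob]	0.0	1000.0	0.0	acetate uptake
FORt_saob	saob	1 for[saob] -> 1 for[e]	0.0	1000.0	0.0	formate export
H2t_saob	saob	1 h2[saob] -> 1 h2[e]	0.0	1000.0	0.0	H2 export
CO2t_saob	saob	1 co2[saob] <-> 1 co2[e]	-1000.0	1000.0	0.0	CO2 diffusion
H2Ot_saob	saob	1 h2o[e] <-> 1 h2o[saob]	-1000.0	1000.0	0.0	water
Ht_saob	saob	1 h[e] <-> 1 h[saob]	-1000.0	1000.0	0.0	proton exchange
MVH_HDR	m1	2 h2[m1] + 1 fdox[m1] + 1 hsds[m1] -> 1 fdred[m1] + 1 com[m1] + 1 cob[m1] + 2 h[m1]	0.0	1000.0	0.0	Mvh-Hdr electron bifurcation
FRH_m1	m1	1 h2[m1] + 1 fo[m1] -> 1 foh2[m1]	0.0	1000.0	0.0	F420-reducing hydrogenase (Frh)
C1TRUNK_m1	m1	1 co2[m1] + 1 mh[m1] + 1 fdred[m1] + 2 foh2[m1] + 2 h[m1] -> 1 m3mh[m1] + 2 h2o[m1] + 1 fdox[m1] + 2 fo[m1]	0.0	1000.0	0.0	Fwd/Ftr/Mch/Mtd/Mer C1 trunk (CO2 -> methyl-H4MPT)
MTR_m1	m1	1 m3mh[m1] + 1 com[m1] -> 1 mcom[m1] + 1 mh[m1] + 0.5239726027 imf[m1]	0.0	1000.0	0.0	Na+-pumping methyl-H4MPT:CoM methyltransferase (Mtr)
MCR_m1	m1	1 mcom[m1] + 1 cob[m1] -> 1 ch4[m1] + 1 hsds[m1]	0.0	1000.0	0.0	methyl-CoM reductase (Mcr)
ATPS_m1	m1	1 adp[m1] + 1 pi[m1] + 1 h[m1] + 1 imf[m1] -> 1 atp[m1] + 1 h2o[m1]	0.0	1000.0	1.0	ATP synthase
ATPM_m1	m1	1 atp[m1] + 1 h2o[m1] -> 1 adp[m1] + 1 pi[m1] + 1 h[m1]	0.0	1000.0	-1.0	ATP yield sink
LEAK_m1	m1	1 imf[m1] -> 	0.0	1000.0	0.0	ion leak
H2t_m1	m1	1 h2[e] -> 1 h2[m1]	0.0	1000.0	0.0	H2 uptake
CH4t_m1	m1	1 ch4[m1] -> 1 ch4[e]	0.0	1000.0	0.0	CH4 release
CO2t_m1	m1	1 co2[e] <-> 1 co2[m1]	-1000.0	1000.0	0.0	CO2 diffusion
H2Ot_m1	m1	1 h2o[m1] <-> 1 h2o[e]	-1000.0	1000.0	0.0	water
Ht_m1	m1	1 h[e] <-> 1 h[m1]	-1000.0	1000.0	0.0	proton exchange
FDH_m2	m2	1 for[m2] + 1 fdox[m2] -> 1 co2[m2] + 1 fdred[m2] + 1 h[m2]	0.0	1000.0	0.0	FdhA formate:ferredoxin oxidoreductase
FRH_m2	m2	1 h2[m2] + 1 fo[m2] -> 1 foh2[m2]	0.0	1000.0	0.0	F420-reducing hydrogenase (Frh)
HDR_F420_m2	m2	1 foh2[m2] + 1 hsds[m2] -> 1 fo[m2] + 1 com[m2] + 1 cob[m2]	0.0	1000.0	0.0	F420H2-dependent heterodisulfide reductase
C1TRUNK_m2	m2	1 co2[m2] + 1 mh[m2] + 1 fdred[m2] + 2 foh2[m2] + 2 h[m2] -> 1 m3mh[m2] + 2 h2o[m2] + 1 fdox[m2] + 2 fo[m2]	0.0	1000.0	0.0	Fwd/Ftr/Mch/Mtd/Mer C1 trunk (CO2 -> methyl-H4MPT)
MTR_m2	m2	1 m3mh[m2] + 1 com[m2] -> 1 mcom[m2] + 1 mh[m2] + 0.6318929939 imf[m2]	0.0	1000.0	0.0	Na+-pumping methyl-H4MPT:CoM methyltransferase (Mtr)
MCR_m2	m2	1 mcom[m2] + 1 cob[m2] -> 1 ch4[m2] + 1 hsds[m2]	0.0	1000.0	0.0	methyl-CoM reductase (Mcr)
ATPS_m2	m2	1 adp[m2] + 1 pi[m2] + 1 h[m2] + 1 imf[m2] -> 1 atp[m2] + 1 h2o[m2]	0.0	1000.0	1.0	ATP synthase
ATPM_m2	m2	1 atp[m2] + 1 h2o[m2] -> 1 adp[m2] + 1 pi[m2] + 1 h[m2]	0.0	1000.0	-1.0	ATP yield sink
LEAK_m2	m2	1 imf[m2] -> 	0.0	1000.0	0.0	ion leak
H2t_m2	m2	1 h2[e] -> 1 h2[m2]	0.0	1000.0	0.0	H2 uptake
CH4t_m2	m2	1 ch4[m2] -> 1 ch4[e]	0.0	1000.0	0.0	CH4 release
CO2t_m2	m2	1 co2[e] <-> 1 co2[m2]	-1000.0	1000.0	0.0	CO2 diffusion
H2Ot_m2	m2	1 h2o[m2] <-> 1 h2o[e]	-1000.0	1000.0	0.0	water
Ht_m2	m2	1 h[e] <-> 1 h[m2]	-1000.0	1000.0	0.0	proton exchange
FORt_m2	m2	1 for[e] -> 1 for[m2]	0.0	1000.0	0.0	formate uptake (FdhC)
EX_ac	exchange	1 ac[e] -> 	-1.0	-1.0	0.0	acetate feed (fixed basis)
EX_ch4	exchange	1 ch4[e] -> 	0.0	1000.0	0.0	methane evolution
EX_co2	exchange	1 co2[e] <-> 	-1000.0	1000.0	0.0	CO2 exchange
EX_h2o	exchange	1 h2o[e] <-> 	-1000.0	1000.0	0.0	water
EX_h	exchange	1 h[e] <-> 	-1000.0	1000.0	0.0	proton exchange
EX_h2	exchange	1 h2[e] -> 	0.0	0.0	0.0	H2 (closed)
EX_for	exchange	1 for[e] -> 	0.0	0.0	0.0	formate (closed)
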