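# Standard formation energies (kJ/mol, 298.15 K) with formation enthalpies
# for temperature adjustment via Gibbs-Helmholtz.
# Values follow the standard anaerobic-microbiology compilation of Thauer,
# Jungermann & Decker (1977), Bacteriol. Rev. 41:100, supplemented with NBS
# tables for enthalpies. Chemical (untransformed) convention at 298.15 K;
# pH enters through the proton activity of the reaction quotient.
species_id	phase	dGf0_kj_mol	dHf0_kj_mol	note
acetate	aqueous	-369.41	-486.01	acetate anion CH3COO-
formate	aqueous	-351.04	-425.55	formate anion HCOO-
co2	gas	-394.36	-393.51	carbon dioxide (g)
ch4	gas	-50.75	-74.81	methane (g)
h2	gas	0.0	0.0	dihydrogen (g)
h2o	aqueous	-237.18	-285.83	liquid water (activity 1)
h	aqueous	0.0	0.0	proton (activity from pH)
co2_aq	aqueous	-386.02	-413.80	dissolved CO2
hco3	aqueous	-586.85	-692.00	bicarbonate
ch4_aq	aqueous	-34.33	-89.04	dissolved methane
h2_aq	aqueous	17.57	-4.20	dissolved dihydrogen
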