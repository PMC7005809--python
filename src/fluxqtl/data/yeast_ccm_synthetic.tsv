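# Reduced compartmented network of yeast central carbon metabolism under
# anaerobic wine-fermentation conditions (68 reactions, 61 metabolites).
# Synthetic reconstruction: the 20 pathway-representative reactions and the
# biomass composition follow the published reduced wine-yeast network; the
# remaining reactions are reconstructed from standard yeast biochemistry.
# Compartments: [c] cytosol, [m] mitochondria; excretion = pure drains (_t),
# mitochondrial transport = _tm. Consumed metabolites are on the left.
id	equation	reversible	lb	ub	pathway
Glc_t	→ glc[c]	0			uptake
Nh4_t	→ nh4[c]	0			uptake
Glc_G6p	glc[c] + atp[c] → g6p[c] + adp[c]	0			uptake
G6p_F6p	g6p[c] ⇌ f6p[c]	1			upper_glycolysis
F6p_Fdp	f6p[c] + atp[c] → fdp[c] + adp[c]	0			upper_glycolysis
Fdp_G3p	fdp[c] ⇌ dhap[c] + g3p[c]	1			upper_glycolysis
Dhap_G3p	dhap[c] ⇌ g3p[c]	1			upper_glycolysis
G3p_13dpg	g3p[c] + nad[c] ⇌ 13dpg[c] + nadh[c]	1			lower_glycolysis
13dpg_3pg	13dpg[c] + adp[c] ⇌ 3pg[c] + atp[c]	1			lower_glycolysis
3pg_2pg	3pg[c] ⇌ 2pg[c]	1			lower_glycolysis
2pg_Pep	2pg[c] ⇌ pep[c]	1			lower_glycolysis
Pep_Pyr	pep[c] + adp[c] → pyr[c] + atp[c]	0			lower_glycolysis
G6p_6pgl	g6p[c] + nadp[c] ⇌ 6pgl[c] + nadph[c]	1			ppp
6pgl_6pgc	6pgl[c] → 6pgc[c]	0			ppp
6pgc_Ru5p	6pgc[c] + nadp[c] → ru5p[c] + CO2[c] + nadph[c]	0			ppp
Ru5p_R5p	ru5p[c] ⇌ r5p[c]	1			ppp
Ru5p_X5p	ru5p[c] ⇌ x5p[c]	1			ppp
R5p_S7p	r5p[c] + x5p[c] ⇌ s7p[c] + g3p[c]	1			ppp
S7p_F6p	s7p[c] + g3p[c] ⇌ e4p[c] + f6p[c]	1			ppp
X5p_F6p	x5p[c] + e4p[c] ⇌ f6p[c] + g3p[c]	1			ppp
Dhap_Glyc3p	dhap[c] + nadh[c] → glyc3p[c] + nad[c]	0			glycerol_synthesis
Glyc3p_Glyc	glyc3p[c] → glyc[c]	0			glycerol_synthesis
Pyr_Acald	pyr[c] → acald[c] + CO2[c]	0			ethanol_synthesis
Acald_Eth	acald[c] + nadh[c] → etoh[c] + nad[c]	0			ethanol_synthesis
Acald_Eth_m	acald[m] + nadh[m] ⇌ etoh[m] + nad[m]	1			ethanol_synthesis
Acald_Ac	acald[c] + nadp[c] → ac[c] + nadph[c]	0			acetate_metabolism
Acald_Ac_m	acald[m] + nadp[m] → ac[m] + nadph[m]	0			acetate_metabolism
Ac_Accoa	ac[c] + 2 atp[c] → accoa[c] + 2 adp[c]	0			accoa_metabolism
Ac_Accoa_m	ac[m] + 2 atp[m] → accoa[m] + 2 adp[m]	0			accoa_metabolism
Pyr_Oaa	pyr[c] + atp[c] + CO2[c] → oaa[c] + adp[c]	0			tca_reductive
Oaa_Mal	oaa[c] + nadh[c] ⇌ mal[c] + nad[c]	1			tca_reductive
Mal_Fum	mal[c] ⇌ fum[c]	1			tca_reductive
Fum_Succ	fum[c] + nadh[c] → succ[c] + nad[c]	0			tca_reductive
Oaa_Mal_m	oaa[m] + nadh[m] ⇌ mal[m] + nad[m]	1			tca_reductive
Mal_Fum_m	mal[m] ⇌ fum[m]	1			tca_reductive
Fum_Succ_m	fum[m] + nadh[m] → succ[m] + nad[m]	0			tca_reductive
Pyr_Accoa_m	pyr[m] + nad[m] → accoa[m] + CO2[m] + nadh[m]	0			tca_oxidative
Oaa_Cit_m	accoa[m] + oaa[m] → cit[m]	0			tca_oxidative
Cit_Icit_m	cit[m] ⇌ icit[m]	1			tca_oxidative
Icit_Akg_m_nad	icit[m] + nad[m] → akg[m] + CO2[m] + nadh[m]	0			tca_oxidative
Icit_Akg_m_nadp	icit[m] + nadp[m] → akg[m] + CO2[m] + nadph[m]	0			tca_oxidative
Akg_Succoa_m	akg[m] + nad[m] → succoa[m] + CO2[m] + nadh[m]	0			tca_oxidative
Succoa_Succ_m	succoa[m] + adp[m] → succ[m] + atp[m]	0			tca_oxidative
Akg_Glu	akg[c] + nh4[c] + nadph[c] → glu[c] + nadp[c]	0			glutamate_cycle
Glu_Akg	glu[c] + nad[c] → akg[c] + nh4[c] + nadh[c]	0			glutamate_cycle
Akg_Glu_m	akg[m] + nh4[m] + nadph[m] → glu[m] + nadp[m]	0			glutamate_cycle
Pyr_tm	pyr[c] ⇌ pyr[m]	1			transport_mito
Oaa_tm	oaa[c] ⇌ oaa[m]	1			transport_mito
Acald_tm	acald[c] ⇌ acald[m]	1			transport_mito
Eth_tm	etoh[c] ⇌ etoh[m]	1			transport_mito
Succ_tm	succ[m] ⇌ succ[c]	1			transport_mito
Mal_tm	mal[c] ⇌ mal[m]	1			transport_mito
Akg_tm	akg[c] ⇌ akg[m]	1			transport_mito
Cit_tm	cit[m] ⇌ cit[c]	1			transport_mito
CO2_tm	CO2[m] ⇌ CO2[c]	1			transport_mito
Nh4_tm	nh4[c] ⇌ nh4[m]	1			transport_mito
Glu_tm	glu[c] ⇌ glu[m]	1			transport_mito
Atp_tm	atp[m] + adp[c] ⇌ atp[c] + adp[m]	1			transport_mito
Eth_t	etoh[c] →	0			excretion
Ac_t	ac[c] →	0			excretion
Pyr_t	pyr[c] →	0			excretion
Akg_t	akg[c] →	0			excretion
Succ_t	succ[c] →	0			excretion
Glyc_t	glyc[c] →	0			excretion
CO2_t	CO2[c] ⇌	1			excretion
Cit_t	cit[c] →	0			excretion
Atp_Adp	atp[c] → adp[c]	0			energy
BIOMASS	3.96 g6p[c] + 0.258 r5p[c] + 0.129 e4p[c] + 0.116 g3p[c] + 0.303 3pg[c] + 0.232 pep[c] + 0.775 oaa[c] + 1.084 pyr[m] + 0 pyr[c] + 0.176 accoa[m] + 0.252 accoa[c] + 0.106 akg[m] + 0.366 akg[c] + 0 CO2[c] + 0.136 glu[c] + 115 atp[c] + 0.106 atp[m] + 1.499 nad[c] + 0.176 nad[m] + 0.602 nadph[m] + 5.35 nadph[c] → 115 adp[c] + 0.106 adp[m] + 1.499 nadh[c] + 0.176 nadh[m] + 0.602 nadp[m] + 5.35 nadp[c]	0			biomass
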