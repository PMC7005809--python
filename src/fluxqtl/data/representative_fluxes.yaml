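# Default selection of pathway-representative fluxes (20 reactions).
# Rules: first = first reaction of the pathway in model order,
#        last  = last reaction of the pathway in model order,
#        explicit = the listed reaction ids (parallel routes kept).
# Convention: excretion fluxes represent extracellular products directly;
# pathways are represented by their first flux, except lower glycolysis
# (last flux), and parallel routes to the same product are all kept.
selection:
  - pathway: upper_glycolysis
    rule: first            # G6p_F6p
  - pathway: lower_glycolysis
    rule: last             # Pep_Pyr
  - pathway: ppp
    rule: first            # G6p_6pgl
  - pathway: ethanol_synthesis
    rule: explicit         # both cytosolic steps and the parallel mitochondrial route
    ids: [Pyr_Acald, Acald_Eth, Acald_Eth_m]
  - pathway: acetate_metabolism
    rule: first            # Acald_Ac
  - pathway: accoa_metabolism
    rule: first            # Ac_Accoa
  - pathway: tca_reductive
    rule: first            # Pyr_Oaa
  - pathway: tca_oxidative
    rule: explicit         # first flux plus both parallel AKG-forming routes
    ids: [Oaa_Cit_m, Icit_Akg_m_nad, Icit_Akg_m_nadp]
  - pathway: excretion
    rule: explicit         # excretion fluxes of the measured products
    ids: [Eth_t, Ac_t, Pyr_t, Akg_t, Succ_t, Glyc_t, CO2_t]
  - pathway: biomass
    rule: first            # BIOMASS
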