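# Metabolite declarations for the packaged CCM network (61 species).
id	name	compartment
glc[c]	glucose	cytosol
g6p[c]	glucose 6-phosphate	cytosol
f6p[c]	fructose 6-phosphate	cytosol
fdp[c]	fructose 1,6-bisphosphate	cytosol
dhap[c]	dihydroxyacetone phosphate	cytosol
g3p[c]	glyceraldehyde 3-phosphate	cytosol
13dpg[c]	1,3-bisphosphoglycerate	cytosol
3pg[c]	3-phosphoglycerate	cytosol
2pg[c]	2-phosphoglycerate	cytosol
pep[c]	phosphoenolpyruvate	cytosol
pyr[c]	pyruvate	cytosol
acald[c]	acetaldehyde	cytosol
etoh[c]	ethanol	cytosol
ac[c]	acetate	cytosol
accoa[c]	acetyl-CoA	cytosol
oaa[c]	oxaloacetate	cytosol
mal[c]	malate	cytosol
fum[c]	fumarate	cytosol
succ[c]	succinate	cytosol
cit[c]	citrate	cytosol
akg[c]	alpha-ketoglutarate	cytosol
glu[c]	glutamate	cytosol
nh4[c]	ammonium	cytosol
glyc3p[c]	glycerol 3-phosphate	cytosol
glyc[c]	glycerol	cytosol
6pgl[c]	6-phosphogluconolactone	cytosol
6pgc[c]	6-phosphogluconate	cytosol
ru5p[c]	ribulose 5-phosphate	cytosol
r5p[c]	ribose 5-phosphate	cytosol
x5p[c]	xylulose 5-phosphate	cytosol
s7p[c]	sedoheptulose 7-phosphate	cytosol
e4p[c]	erythrose 4-phosphate	cytosol
CO2[c]	carbon dioxide	cytosol
atp[c]	ATP	cytosol
adp[c]	ADP	cytosol
nad[c]	NAD+	cytosol
nadh[c]	NADH	cytosol
nadp[c]	NADP+	cytosol
nadph[c]	NADPH	cytosol
pyr[m]	pyruvate	mitochondria
acald[m]	acetaldehyde	mitochondria
etoh[m]	ethanol	mitochondria
ac[m]	acetate	mitochondria
accoa[m]	acetyl-CoA	mitochondria
oaa[m]	oxaloacetate	mitochondria
cit[m]	citrate	mitochondria
icit[m]	isocitrate	mitochondria
akg[m]	alpha-ketoglutarate	mitochondria
succoa[m]	succinyl-CoA	mitochondria
succ[m]	succinate	mitochondria
fum[m]	fumarate	mitochondria
mal[m]	malate	mitochondria
glu[m]	glutamate	mitochondria
nh4[m]	ammonium	mitochondria
CO2[m]	carbon dioxide	mitochondria
atp[m]	ATP	mitochondria
adp[m]	ADP	mitochondria
nad[m]	NAD+	mitochondria
nadh[m]	NADH	mitochondria
nadp[m]	NADP+	mitochondria
nadph[m]	NADPH	mitochondria
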