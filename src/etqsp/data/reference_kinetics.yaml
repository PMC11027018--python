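# Reference ET-1 kinetics ("reference kinetics" of the package).
#
# Chosen so that: baseline plasma ET-1 is ~2 pM; a stepped 0.2/0.4/0.8
# pmol/kg/min infusion raises plasma ET-1 roughly 2-4x; the ET_B receptor
# carries the large majority of receptor-mediated clearance (so ET_B
# blockade raises circulating ET-1 markedly while ET_A blockade raises it
# only mildly); and renal (tissue) ET_B density greatly exceeds ET_A.
# Units: pM, L, 1/min, 1/pM/min.
bigET1_production_rate: 3.4007
k_ECE: 0.2
k_tp: 1.33
k_pt: 5.0
V_tissue: 12.0
V_plasma: 3.0
kon_A: 0.05
koff_A: 1.05
kon_B: 0.008
koff_B: 0.4
k_int_A: 0.2
k_int_B: 2.0
R_A_tissue: 6.5
R_B_tissue: 200.0
R_A_plasma: 6.0
R_B_plasma: 25.0
k_cl_plasma: 0.6
weight_kg: 70.0
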