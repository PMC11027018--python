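# Receptor antagonists. Kd in pM, half-life in min, molar mass in g/mol.
# BQ123 and VML588 are ET_A-selective; BQ788 is ET_B-selective. VML588
# affinity and PK are not published with the protocol that used it; the
# values below are chosen so its 0.05/0.2/0.4 mg/kg/hr arms span a graded
# (roughly 50-90%) ET_A blockade.
BQ123:
  Kd_A: 7300.0
  Kd_B: 7300000.0
  plasma_halflife: 10.0
  molar_mass: 611.0
  eta_selective: true
BQ788:
  Kd_A: 1300000.0
  Kd_B: 1200.0
  plasma_halflife: 10.0
  molar_mass: 664.0
  eta_selective: false
VML588:
  Kd_A: 3000000.0
  Kd_B: 3000000000.0
  plasma_halflife: 60.0
  molar_mass: 500.0
  eta_selective: true
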