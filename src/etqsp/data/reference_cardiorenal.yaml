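# Healthy-human cardiorenal operating point. Dependent parameters (K_f,
# eta_CD, eta_dw) are derived at load time so this point is an exact steady
# state: MAP 93 mmHg, GFR 120 mL/min, RBF 1.1 L/min, CO 5 L/min, plasma Na
# 140 mmol/L, urine flow 1 mL/min at the stated sodium/water intake.
targets:
  MAP0: 93.0
  GFR0_ml_min: 120.0
  RBF0: 1.1
  CO0: 5.0
  plasma_Na0: 140.0
  Na_intake: 150.0
  water_intake_ml_min: 1.0
  urine0_ml_min: 1.0
  frac_pre: 0.33
  frac_aff: 0.15
  frac_eff: 0.40
  eta_PT: 0.70
  eta_LoH: 0.75
  eta_DCT: 0.60
  pi_in: 25.7
  P_bowman: 10.0
  P_renal_vein: 4.0
  hematocrit: 0.45
overrides: {}
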