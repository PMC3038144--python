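# Registry of linear energy-requirement prediction equations for infants
# 0-3 years.  Each entry predicts a whole-body daily rate in kcal/d as
#   weight_coef * WT(kg) + length_coef * L(cm) + intercept
# Equations published with a length term in metres-per-100 form have the
# coefficient converted to per-cm here (printed 1517.4 x (L/100) -> 15.174/cm).
# `target` names the directly measured quantity each equation estimates:
# 24-h energy expenditure (EE24), resting (RMR) or sleeping (SMR) metabolic
# rate; the WHO/Schofield/Oxford basal-rate equations map to RMR.
version: 1
equations:
  - {name: EMTACEE-WT,   sex: any,    target: EE24, weight_coef: 98.1, length_coef: 0.0,    intercept: -121.7}
  - {name: EMTACEE-LWT,  sex: any,    target: EE24, weight_coef: 73.3, length_coef: 10.7,   intercept: -635.1}
  - {name: EMTACRMR-WT,  sex: any,    target: RMR,  weight_coef: 84.5, length_coef: 0.0,    intercept: -117.3}
  - {name: EMTACRMR-LWT, sex: any,    target: RMR,  weight_coef: 61.0, length_coef: 10.1,   intercept: -605.1}
  - {name: EMTACSMR-WT,  sex: any,    target: SMR,  weight_coef: 73.3, length_coef: 0.0,    intercept: -72.6}
  - {name: EMTACSMR-LWT, sex: any,    target: SMR,  weight_coef: 55.6, length_coef: 7.6,    intercept: -440.7}
  - {name: WHO,          sex: male,   target: RMR,  weight_coef: 60.9, length_coef: 0.0,    intercept: -54.0}
  - {name: WHO,          sex: female, target: RMR,  weight_coef: 61.0, length_coef: 0.0,    intercept: -51.0}
  - {name: SCH-WT,       sex: male,   target: RMR,  weight_coef: 59.5, length_coef: 0.0,    intercept: -30.3}
  - {name: SCH-WT,       sex: female, target: RMR,  weight_coef: 58.3, length_coef: 0.0,    intercept: -31.1}
  - {name: SCH-LWT,      sex: male,   target: RMR,  weight_coef: 0.2,  length_coef: 15.174, intercept: -617.6}
  - {name: SCH-LWT,      sex: female, target: RMR,  weight_coef: 16.3, length_coef: 10.232, intercept: -413.5}
  - {name: OXFORD-WT,    sex: male,   target: RMR,  weight_coef: 61.0, length_coef: 0.0,    intercept: -33.7}
  - {name: OXFORD-WT,    sex: female, target: RMR,  weight_coef: 58.9, length_coef: 0.0,    intercept: -23.1}
  - {name: OXFORD-LWT,   sex: male,   target: RMR,  weight_coef: 28.2, length_coef: 8.59,   intercept: -371.0}
  - {name: OXFORD-LWT,   sex: female, target: RMR,  weight_coef: 30.4, length_coef: 7.03,   intercept: -287.0}
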