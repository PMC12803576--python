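# Plasma scenario presets (mmol/L; insulin and catecholamine in arbitrary
# units).  The fasting free-fatty-acid level of 0.5 mmol/L anchors the
# physiological overnight-fasting state; postprandial and diabetic-fasting
# values are config-declared stand-ins a user may override.
fasting:
  glucose: 5.0
  fatty_acids: 0.5
  lactate: 1.0
  pyruvate: 0.1
  beta_hydroxybutyrate: 0.15
  acetoacetate: 0.05
  bcaa: 0.4
  insulin: 40.0
  catecholamine: 10.0
  potassium: 4.5
  sodium: 140.0
  calcium: 1.2

postprandial:
  glucose: 7.5
  fatty_acids: 0.3
  lactate: 1.2
  pyruvate: 0.12
  beta_hydroxybutyrate: 0.05
  acetoacetate: 0.02
  bcaa: 0.6
  insulin: 200.0
  catecholamine: 10.0
  potassium: 4.5
  sodium: 140.0
  calcium: 1.2

diabetic_fasting:
  glucose: 9.0
  fatty_acids: 0.7
  lactate: 1.2
  pyruvate: 0.12
  beta_hydroxybutyrate: 0.3
  acetoacetate: 0.1
  bcaa: 0.5
  insulin: 20.0
  catecholamine: 10.0
  potassium: 4.5
  sodium: 140.0
  calcium: 1.2
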