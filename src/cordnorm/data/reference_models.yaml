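# Published residual-normalization models for spinal cord areas in healthy
# adults (32-subject reference cohort, ages 28-78).  Coefficients are in
# outcome units (mm²) per covariate unit (age: years; ticv: mm³; vertebra
# metrics: mm / mm²).  Covariate means are the reference-cohort means frozen
# into the residual formula.  adj_r2 is the published adjusted R² of the fit
# (null where the publication reports none, i.e. the model failed the
# adjusted-R² > 0.35 retention gate at that level).
n: 32
covariate_means:
  age: 48.84
  ticv: 1434165.26
  ap_vertebra_diameter: 15.63
  sagittal_vertebra_area: 199.93
models:
  "C2-C3:tca:model1":
    outcome: "C2-C3:tca"
    coefficients:
      ticv: 2.33e-05
      sagittal_vertebra_area: 0.059
    adj_r2: 0.44
  "C2-C3:tca:model2":
    outcome: "C2-C3:tca"
    coefficients:
      age: -0.113
      ticv: 2.20e-05
      ap_vertebra_diameter: 0.873
    adj_r2: 0.41
  "C2-C3:tca:model3":
    outcome: "C2-C3:tca"
    coefficients:
      age: -0.105
      ticv: 1.89e-05
      sagittal_vertebra_area: 0.063
    adj_r2: 0.47
  "C2-C3:gm:model1":
    outcome: "C2-C3:gm"
    coefficients:
      ticv: 7.20e-06
      sagittal_vertebra_area: 0.017
    adj_r2: 0.42
  "C2-C3:gm:model2a":
    outcome: "C2-C3:gm"
    coefficients:
      ticv: 7.19e-06
      ap_vertebra_diameter: 0.466
    adj_r2: 0.50
  "C3-C4:tca:model3":
    outcome: "C3-C4:tca"
    coefficients:
      age: -0.150
      ticv: 1.17e-05
      sagittal_vertebra_area: 0.080
    adj_r2: 0.44
  "T8-T9:tca:model3":
    outcome: "T8-T9:tca"
    coefficients:
      age: -0.101
      ticv: 6.58e-06
      sagittal_vertebra_area: 0.027
    adj_r2: 0.42
  "T9-T10:tca:model3":
    outcome: "T9-T10:tca"
    coefficients:
      age: -0.110
      ticv: 6.36e-06
      sagittal_vertebra_area: 0.037
    adj_r2: 0.43
  "C3-C4:tca:model2":
    outcome: "C3-C4:tca"
    coefficients:
      age: -0.153
      ticv: 1.72e-05
      ap_vertebra_diameter: 0.809
    adj_r2: 0.36
  "T8-T9:tca:model2":
    outcome: "T8-T9:tca"
    coefficients:
      age: -0.116
      ticv: 6.52e-06
      ap_vertebra_diameter: 0.709
    adj_r2: 0.56
  "T9-T10:tca:model2":
    outcome: "T9-T10:tca"
    coefficients:
      age: -0.127
      ticv: 6.80e-06
      ap_vertebra_diameter: 0.854
    adj_r2: 0.53
  "C3-C4:gm:model2a":
    outcome: "C3-C4:gm"
    coefficients:
      ticv: 7.70e-06
      ap_vertebra_diameter: 0.172
    adj_r2: 0.37
  "T8-T9:gm:model2a":
    outcome: "T8-T9:gm"
    coefficients:
      ticv: 1.84e-06
      ap_vertebra_diameter: 0.143
    adj_r2: null
  "T9-T10:gm:model2a":
    outcome: "T9-T10:gm"
    coefficients:
      ticv: 4.77e-06
      ap_vertebra_diameter: 0.191
    adj_r2: 0.33
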