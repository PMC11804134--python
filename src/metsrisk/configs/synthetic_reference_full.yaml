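# SYNTHETIC reference model (full variant).
#
# These coefficient values are NOT the published PsyMetRiC coefficients:
# they are plausible stand-ins, chosen once so the simulator and test-suite
# have a fully specified truth model with the published predictor *set*
# (age, sex, ethnicity, smoking, antipsychotic metabolic activity, BMI,
# HDL, triglycerides).  To run the pipeline with the real algorithm,
# transcribe the published coefficient table into a copy of
# psymetric_template.yaml.
name: synthetic_reference_full
variant: full
site: UK
provenance: synthetic plausible coefficients (simulation truth; not the published values)
intercept: -6.7
predictors:
  - name: age
    kind: continuous
    coefficient: 0.085
  - name: sex
    kind: binary
    coefficient: 0.32
    encoding: {female: 0, male: 1}
  - name: ethnicity
    kind: categorical
    coefficient: 0.30
    encoding: {white: 0, non_white: 1}
  - name: smoker
    kind: binary
    coefficient: 0.28
    encoding: {false: 0, true: 1}
  - name: antipsychotic_class
    kind: binary
    coefficient: 0.55
    encoding: {lower_metabolic: 0, higher_metabolic: 1}
  - name: bmi
    kind: continuous
    coefficient: 0.11
  - name: hdl
    kind: continuous
    coefficient: -0.85
  - name: triglycerides
    kind: continuous
    coefficient: 0.32
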