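# Template for the published PsyMetRiC full-model coefficients.
#
# Coefficient values are data, not code.  Fill every `coefficient: null`
# below from the coefficient table of the original open-access PsyMetRiC
# development publication, set `provenance` to the citation, and pass the
# file to metsrisk.risk_model.load_model.  load_model refuses configs with
# null coefficients, so a half-filled template cannot be used by accident.
#
# Encodings fix the reference levels: female, lower-metabolic-activity
# antipsychotic and white ethnicity are the reference (0) categories.
# Continuous predictors enter untransformed unless an explicit
# `encoding: {transform: log}` is added to match the source publication.
name: psymetric_full
variant: full
site: UK
provenance: FILL IN - published coefficient table citation
intercept: null
predictors:
  - name: age
    kind: continuous
    coefficient: null
  - name: sex
    kind: binary
    coefficient: null
    encoding: {female: 0, male: 1}
  - name: ethnicity
    kind: categorical
    coefficient: null
    encoding: {white: 0, non_white: 1}
  - name: smoker
    kind: binary
    coefficient: null
    encoding: {false: 0, true: 1}
  - name: antipsychotic_class
    kind: binary
    coefficient: null
    encoding: {lower_metabolic: 0, higher_metabolic: 1}
  - name: bmi
    kind: continuous
    coefficient: null
  - name: hdl
    kind: continuous
    coefficient: null
  - name: triglycerides
    kind: continuous
    coefficient: null
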