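# SYNTHETIC reference model (partial variant): the full model minus the
# biochemical predictors (HDL, triglycerides), for settings where blood
# results are unavailable.  Coefficients are plausible stand-ins, not the
# published values; see synthetic_reference_full.yaml.
name: synthetic_reference_partial
variant: partial
site: UK
provenance: synthetic plausible coefficients (simulation truth; not the published values)
intercept: -7.4
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
    coefficient: 0.13
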