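drug_name,class
clozapine,higher_metabolic
olanzapine,higher_metabolic
quetiapine,higher_metabolic
risperidone,higher_metabolic
paliperidone,higher_metabolic
zuclopenthixol,higher_metabolic
chlorpromazine,higher_metabolic
aripiprazole,lower_metabolic
amisulpride,lower_metabolic
ziprasidone,lower_metabolic
lurasidone,lower_metabolic
haloperidol,lower_metabolic
cariprazine,lower_metabolic
brexpiprazole,lower_metabolic
flupentixol,lower_metabolic
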