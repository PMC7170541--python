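# Default lexicons for the rule-based extractor.  Editable: load with
# apmonitor.lexicons.load_lexicons(path) to override.
#
# Diagnosis surface terms are grouped by the ICD-10 block they assert.
diagnosis_terms:
  F00-F03:
    - dementia
    - alzheimer's disease
    - alzheimers disease
    - vascular dementia
    - lewy body dementia
    - mixed dementia
    - frontotemporal dementia
  F20-F29:
    - schizophrenia
    - psychosis
    - psychotic disorder
    - schizoaffective disorder
    - delusional disorder
  other-F:
    - depression
    - depressive episode
    - bipolar affective disorder
    - generalised anxiety disorder

# Generic antipsychotic names mapped to their brand synonyms.  All surface
# forms normalise to the generic.
antipsychotics:
  risperidone: [risperdal]
  olanzapine: [zyprexa]
  quetiapine: [seroquel]
  haloperidol: [haldol, serenace]
  aripiprazole: [abilify]
  amisulpride: [solian]
  sulpiride: []
  promazine: []
  clozapine: [clozaril]
  chlorpromazine: [largactil]
  zuclopenthixol: [clopixol]
  paliperidone: [invega]
  lurasidone: [latuda]

start_phrases: [started, start, commenced, initiated]
stop_phrases: [stopped, stop, discontinued, ceased, withheld, withdrawn]
negation_cues: [no, not, denies, no evidence of]
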