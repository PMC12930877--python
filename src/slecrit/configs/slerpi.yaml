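# SLERPI (SLE Risk Probability Index), dichotomized scoring rule.
# Fourteen weighted clinical and immunologic items; each item scores when
# present AND not better explained by an alternative diagnosis.  The total
# ranges 0-14; a total >= 7 classifies the patient as SLE.
#
# The weights below are maintained as editable configuration: they satisfy
# the rule's published structure (14 items, maximum total exactly 14,
# half-point granularity so that sub-threshold totals such as 6.5 occur) and
# should be reconciled against the primary scoring table when deploying on
# real data.  The engine reads only this file, so corrections require no
# code change.
system: slerpi
label: SLERPI
rule: weighted_sum
threshold: 7
max_score: 14
attribution_gated: true
items:
  - {name: malar_or_maculopapular_rash, any_of: [acute_cutaneous], weight: 2.0}
  - {name: subacute_or_discoid_lupus, any_of: [subacute_cutaneous, chronic_cutaneous], weight: 1.0}
  - {name: oral_nasal_ulcers, any_of: [oral_nasal_ulcers], weight: 0.5}
  - {name: alopecia, any_of: [alopecia], weight: 1.0}
  - {name: arthritis, any_of: [arthritis], weight: 0.5}
  - {name: serositis, any_of: [serositis_pleural, serositis_pericardial], weight: 1.0}
  - {name: proteinuria, any_of: [proteinuria], weight: 1.5}
  - {name: neurologic_involvement, any_of: [seizure, psychosis, delirium, other_neuro], weight: 1.0}
  - {name: unexplained_fever, any_of: [fever], weight: 0.5}
  - {name: leukopenia_or_lymphopenia, any_of: [leukopenia, lymphopenia], weight: 0.5}
  - {name: immune_cytopenia, any_of: [thrombocytopenia, hemolytic_anemia], weight: 1.0}
  - {name: ana, any_of: [ana_positive], weight: 2.0}
  - {name: anti_dsdna, any_of: [anti_dsdna], weight: 1.0}
  - {name: low_complement, any_of: [low_c3, low_c4], weight: 0.5}
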