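# ACR-1997 revised classification criteria for SLE.
# Eleven criteria; classification requires >= 4.  Each item is a disjunction
# over the canonical feature flags (multi-manifestation items collapse to a
# single count).
system: acr1997
label: ACR-1997
rule: count
threshold: 4
attribution_gated: false
items:
  - name: malar_rash
    any_of: [acute_cutaneous]
  - name: discoid_rash
    any_of: [chronic_cutaneous]
  - name: photosensitivity
    any_of: [photosensitivity]
  - name: oral_ulcers
    any_of: [oral_nasal_ulcers]
  - name: arthritis
    any_of: [arthritis]
  - name: serositis
    any_of: [serositis_pleural, serositis_pericardial]
  - name: renal_disorder
    any_of: [proteinuria, lupus_nephritis_biopsy]
  - name: neurologic_disorder
    any_of: [seizure, psychosis]
  - name: hematologic_disorder
    any_of: [hemolytic_anemia, leukopenia, lymphopenia, thrombocytopenia]
  - name: immunologic_disorder
    any_of: [anti_dsdna, anti_sm, antiphospholipid]
  - name: ana
    any_of: [ana_positive]
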