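# EULAR/ACR-2019 classification criteria for SLE.
# Entry criterion: ANA titer >= 1:80 (positional comparison on the titer
# scale).  Additive weighted score over ten domains; within each domain only
# the highest-weighted satisfied item counts.  Classification requires a
# total score >= 10 and at least one contributing clinical-domain item
# (require_clinical can be switched off to apply the bare >= 10 rule).
# Items count only when attributable to SLE (not better explained by an
# alternative diagnosis).
#
# Note on the serosal domain: the canonical feature set records pleural and
# pericardial serositis; both map to the effusion item (weight 5).  A
# separate acute-pericarditis item (weight 6 in the published rule) is not
# representable and is omitted.
# Note on renal biopsies: a biopsy-proven lupus nephritis with no recorded
# histologic class scores the lower biopsy weight (8).
system: eular_acr2019
label: EULAR/ACR-2019
rule: weighted_domains
threshold: 10
entry: ana_titer_ge_1_80
require_clinical: true
attribution_gated: true
domains:
  - name: constitutional
    category: clinical
    items:
      - {name: fever, any_of: [fever], weight: 2}
  - name: hematologic
    category: clinical
    items:
      - {name: leukopenia, any_of: [leukopenia], weight: 3}
      - {name: thrombocytopenia, any_of: [thrombocytopenia], weight: 4}
      - {name: autoimmune_hemolysis, any_of: [hemolytic_anemia], weight: 4}
  - name: neuropsychiatric
    category: clinical
    items:
      - {name: delirium, any_of: [delirium], weight: 2}
      - {name: psychosis, any_of: [psychosis], weight: 3}
      - {name: seizure, any_of: [seizure], weight: 5}
  - name: mucocutaneous
    category: clinical
    items:
      - {name: nonscarring_alopecia, any_of: [alopecia], weight: 2}
      - {name: oral_ulcers, any_of: [oral_nasal_ulcers], weight: 2}
      - {name: subacute_or_discoid_lupus, any_of: [subacute_cutaneous, chronic_cutaneous], weight: 4}
      - {name: acute_cutaneous_lupus, any_of: [acute_cutaneous], weight: 6}
  - name: serosal
    category: clinical
    items:
      - {name: pleural_or_pericardial_effusion, any_of: [serositis_pleural, serositis_pericardial], weight: 5}
  - name: musculoskeletal
    category: clinical
    items:
      - {name: joint_involvement, any_of: [arthritis], weight: 6}
  - name: renal
    category: clinical
    items:
      - {name: proteinuria, any_of: [proteinuria], weight: 4}
      - {name: nephritis_class_II_V, predicate: ln_class_II_V, weight: 8}
      - {name: nephritis_class_III_IV, predicate: ln_class_III_IV, weight: 10}
  - name: antiphospholipid
    category: immunologic
    items:
      - {name: apl_antibodies, any_of: [antiphospholipid], weight: 2}
  - name: complement
    category: immunologic
    items:
      - {name: low_c3_or_low_c4, predicate: low_c3_or_c4, weight: 3}
      - {name: low_c3_and_low_c4, predicate: low_c3_and_c4, weight: 4}
  - name: sle_specific_antibodies
    category: immunologic
    items:
      - {name: anti_dsdna_or_anti_sm, any_of: [anti_dsdna, anti_sm], weight: 6}
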