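# Default synthetic cohort profile.
#
# Emulates a two-group cross-sectional cohort: expert-confirmed SLE cases
# versus other-rheumatic-disease controls (a pooled group dominated by RA,
# systemic sclerosis and Behcet's disease).  Group sizes, female fractions,
# age/onset/duration moments and the headline feature margins (proteinuria,
# acute rash, alopecia, ANA, neurologic subtypes) follow the published
# cohort characteristics; margins the source tables do not print are set to
# values typical of SLE vs mixed rheumatic-disease control panels and are
# documented in docs/methods.md.
#
# Features are Bernoulli per group, correlated through one standard-normal
# latent severity per patient via a Gaussian-copula threshold (coupling = 0
# recovers independence; marginal prevalences are exact for any coupling).
n_cases: 655
n_controls: 626
seed: 20260921
coupling: 0.5

female_fraction: {case: 0.934, control: 0.783}

onset_age:
  case: {mean: 25.7, sd: 8.5}
  control: {mean: 33.8, sd: 10.8}

# duration ~ LogNormal(mu, sigma), years.  Case parameters reproduce the
# printed mean (7.2 y) and an early-disease (<= 1 y) fraction of ~ 99/655.
duration_lognormal:
  case: {mu: 1.246, sigma: 1.207}
  control: {mu: 1.876, sigma: 0.727}

# exact stratification: this fraction of cases is drawn from the duration
# distribution conditional on <= 1 year (99 of 655 by default); null
# disables stratification.
early_case_fraction: 0.15114503816793893

# P(histologic class III/IV | biopsy-proven lupus nephritis)
ln_class_iii_iv_fraction: 0.6

ana_titer_given_positive:
  case: {"1:80": 0.05, "1:160": 0.20, "1:320": 0.30, "1:640": 0.25, "1:1280": 0.20}
  control: {"1:80": 0.45, "1:160": 0.35, "1:320": 0.15, "1:640": 0.04, "1:1280": 0.01}

features:  # prevalence {case, control}
  acute_cutaneous:        {case: 0.745, control: 0.048}
  subacute_cutaneous:     {case: 0.080, control: 0.010}
  chronic_cutaneous:      {case: 0.115, control: 0.020}
  photosensitivity:       {case: 0.550, control: 0.060}
  oral_nasal_ulcers:      {case: 0.400, control: 0.080}
  alopecia:               {case: 0.664, control: 0.110}
  arthritis:              {case: 0.750, control: 0.550}
  serositis_pleural:      {case: 0.200, control: 0.040}
  serositis_pericardial:  {case: 0.180, control: 0.030}
  proteinuria:            {case: 0.609, control: 0.019}
  lupus_nephritis_biopsy: {case: 0.280, control: 0.002}
  seizure:                {case: 0.121, control: 0.010}
  psychosis:              {case: 0.020, control: 0.005}
  delirium:               {case: 0.034, control: 0.005}
  other_neuro:            {case: 0.058, control: 0.020}
  hemolytic_anemia:       {case: 0.080, control: 0.010}
  leukopenia:             {case: 0.250, control: 0.050}
  lymphopenia:            {case: 0.250, control: 0.060}
  thrombocytopenia:       {case: 0.150, control: 0.040}
  fever:                  {case: 0.350, control: 0.100}
  ana_positive:           {case: 0.992, control: 0.417}
  anti_dsdna:             {case: 0.680, control: 0.040}
  anti_sm:                {case: 0.280, control: 0.020}
  antiphospholipid:       {case: 0.300, control: 0.100}
  low_c3:                 {case: 0.500, control: 0.050}
  low_c4:                 {case: 0.420, control: 0.040}
  coombs_positive:        {case: 0.150, control: 0.020}
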