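# Methods

## Patient record and missing data

A record carries demographics (sex, age at enrollment, age at symptom
onset, disease duration in years), a tri-state flag (present / absent /
unknown) for each of 27 clinical and immunologic features, an ordered
categorical ANA titer (`negative, 1:80, 1:160, 1:320, 1:640, 1:1280`), and
the expert reference diagnosis. Invariants enforced at construction: onset
age ≤ enrollment age, duration ≥ 0, unique patient ids per cohort. The
derived early-disease flag is `duration ≤ 1.0` year, inclusive.

Every engine treats `unknown` as `absent`. This is a deliberate,
conservative convention: a validation cohort assembled for criteria
comparison excludes participants with inadequate documentation, so engines
should never see structural missingness; the distinct `unknown` state
exists so real data can be audited before scoring. Titer comparisons
(`≥ 1:80`) are positional on the configured level list, never numeric
parsing of the label.

Cohort files are comma-delimited UTF-8 with a fixed column order; tri-state
flags serialize as `1/0/NA`. Floats are written at 6 significant digits and
the generator rounds ages/durations to 2 decimals, so write → read → write
is byte-identical.

## Rule engines

All four engines are pure functions of a record, driven by YAML weight
tables validated at load. Each returns a continuous score, the binary
classification, and an item-level breakdown whose contributed weights sum
exactly to the score.

* **ACR-1997** — count of 11 items, threshold ≥ 4. Multi-manifestation
  items (hematologic, neurologic, serositis, renal, immunologic) are
  disjunctions that count once.
* **SLICC-2012** — count of 17 items (11 clinical, 6 immunologic),
  threshold ≥ 4 with ≥ 1 clinical and ≥ 1 immunologic, plus the nephritis
  shortcut: biopsy-proven lupus nephritis with ANA or anti-dsDNA classifies
  regardless of count. The original SLICC wording counts a positive direct
  Coombs only in the absence of hemolytic anemia; because that conditioning
  makes classification non-monotone under feature flips, the shipped
  default counts Coombs unconditionally and the config flag
  `coombs_requires_no_hemolysis` restores the stricter wording.
* **EULAR/ACR-2019** — entry requires ANA titer ≥ 1:80 (an unknown or
  negative titer fails entry; the binary ANA flag is not consulted).
  Weighted domains with per-domain maximum: a domain contributes only its
  highest-weighted satisfied item. Classification requires total ≥ 10 and
  at least one contributing clinical-domain item; the `require_clinical`
  switch can disable the side condition to apply a bare ≥ 10 rule. Two
  representational conventions: both serositis flags map to the effusion
  item (weight 5; a separate acute-pericarditis item is not representable
  in the feature set), and a biopsy-proven nephritis without a recorded
  histologic class scores the lower biopsy weight (8) rather than 10.
* **SLERPI** — weighted sum of 14 items, range 0–14, threshold ≥ 7
  (a total of exactly 7 classifies). The shipped weight table is editable
  configuration satisfying the rule's published structure — 14 items over
  the documented feature list, half-point granularity, maximum total
  exactly 14, sub-threshold totals such as 6.5 realizable — and should be
  reconciled against the primary scoring table before use on real data;
  the engine reads only the YAML, so corrections need no code change.

Attribution (`not better explained by an alternative diagnosis`) gates
EULAR/ACR-2019 and SLERPI items only, matching the wording of those two
rules; ACR-1997 and SLICC-2012 ignore it. With attribution fixed true, all
four engines are monotone: flipping any flag from absent to present never
lowers a score and never revokes a classification (fuzz-tested on 10,000
random records).

## Diagnostic accuracy

Sensitivity, specificity, PPV, NPV and accuracy come with exact
Clopper–Pearson intervals from Beta quantiles
(`Beta(x, n−x+1)` / `Beta(x+1, n−x)` at α/2 and 1−α/2), with the bounds
pinned to 0 and 1 at x = 0 and x = n. Accuracy uses the same interval on
the full denominator. A zero-denominator ratio is reported as
not-available, never as a silent zero.

ROC AUC is the Mann–Whitney estimator with midrank tie handling; the CI is
a Wald interval using the DeLong variance from placement values, truncated
to [0, 1]. A dichotomized rule's AUC is identically
(sensitivity + specificity)/2 — roughly 0.76–0.93 for these engines —
whereas the engines' continuous scores give AUCs in the high 0.95–0.99
range; published AUCs of that magnitude can only arise from a continuous
score, so `evaluate` uses the continuous score by default and the binary
variant remains computable.

Two-group descriptives use Student's t (pooled variance) for continuous
variables and the Pearson chi-square without continuity correction for
binary ones (the default output line of the major commercial packages;
configurable at the call site).

NRI is the binary two-category form. Among cases, "up" (old-negative,
new-positive) is beneficial; among controls "up" is a new false positive
and counts against the new classifier. `nri_total = nri_events +
nri_nonevents` holds exactly, `nri_total(a,b) = −nri_total(b,a)`, and
`nri_events · n_cases` equals the false-negative difference between the
two classifiers — all used as invariant tests.

Subgroups defined on case attributes (early disease, duration strata,
organ involvement) keep the full control panel, so subgroup sensitivity is
comparable against an unchanged specificity base; sex strata filter both
groups.

## Concordance, discordance, clustering

Combination counts use exact-pattern (UpSet) semantics over the 16 possible
positive-classification patterns among reference-positive patients; counts
conserve the case total. Missed-case analysis produces per-system miss
sets, pairwise overlaps, per-case miss multiplicity (0–4) and per-system
feature prevalence among missed cases.

Discordant cases (reference-positive, missed by ≥ 1 system) are clustered
on their raw binary feature vectors — all flags, unscaled — with Ward's
method implemented from scratch: squared-Euclidean initial distances,
Lance–Williams updates, merge heights reported as √(2·ΔESS) (the
Euclidean-scale "ward.D2" convention, under which merging two singletons
happens at their Euclidean distance). Ties in the minimum-merge selection
break on the lowest (left-id, right-id) pair, making trees deterministic
for a given row order; on tie-free (generic-position) data the partition is
also row-order invariant. The implementation is verified against an O(n⁴)
from-scratch agglomeration that recomputes the Ward objective at every
step (all n ≤ 12 fixtures) and cross-checked against an independent
library implementation via cophenetic distances on generic-position data.
Cutting at k removes the k−1 highest merges; labels are renumbered by
descending cluster size. k defaults to 4 but is always user-specified; no
automatic model selection is claimed.

## Synthetic cohorts

The generator emulates a two-group cross-sectional validation cohort:
expert-confirmed SLE cases versus a pooled other-rheumatic-disease control
group. Per group it draws sex, onset age (normal, clipped at 5 y),
disease duration (log-normal), and the feature vector. Features are
Bernoulli with configured per-group prevalence, correlated through a
single standard-normal latent severity per patient in a Gaussian copula:

    s_if = c·z_i + √(1−c²)·ε_if,   present ⇔ s_if > −Φ⁻¹(p_f)

so marginal prevalences are exact for any coupling c ∈ [0, 1] and c = 0
recovers independence. The ANA titer is sampled conditional on the ANA
flag (cases skew to high titers, controls to low), the nephritis histologic
class conditional on a positive biopsy. Everything is deterministic given
the seed; identical config + seed reproduces a byte-identical file.

Default profile (`configs/cohort_default.yaml`): 655 cases / 626 controls;
female 93.4% vs 78.3%; onset 25.7 ± 8.5 vs 33.8 ± 10.8 y; and the
headline margins (proteinuria 60.9% vs 1.9%, acute rash 74.5% vs 4.8%,
alopecia 66.4% vs 11.0%, ANA 99.2% vs 41.7%, neurologic subtype rates,
chronic cutaneous ~11.5%). Margins not reported anywhere were set once to
values typical of SLE versus mixed rheumatic-disease panels (e.g.
arthritis 75% vs 55% — the control group is RA-heavy; anti-dsDNA 68% vs
4%; low C3 50% vs 5%) and are documented in the config file. Coupling
defaults to 0.5.

Two deliberate compromises:

* **Duration.** A two-parameter log-normal cannot simultaneously match the
  cases' reported mean (7.2 y), SD (6.3 y) and an early-disease share of
  99/655. The default matches the mean and the early share (μ = 1.246,
  σ = 1.207), accepting an inflated SD (~13 y). When
  `early_case_fraction` is set, stratified inverse-CDF sampling pins the
  early-case count exactly (99 by default).
* **Joint structure.** Only marginal prevalences plus a one-factor
  correlation are emulated. Real SLE patients have strongly structured
  multi-feature phenotypes that concentrate criteria scores well above the
  thresholds; the synthetic profile does not reproduce that, so synthetic
  operating points (e.g. SLERPI sensitivity at the ≥ 7 threshold, NRI
  signs) differ from real-cohort values even though rankings by AUC are
  similar. Passing tests on synthetic data therefore validate the
  *computations*, not any clinical performance claim. Feature prevalence
  shifts between early and established disease, and per-diagnosis control
  subgroups (RA vs SSc vs Behçet), are likewise not modeled.

`plant_discordant_clusters` generates planted-block binary cohorts with
known labels for cluster-recovery experiments; the shipped recovery test
uses sizes (23, 15, 6, 11) with well-separated phenotype profiles and
requires Rand index ≥ 0.9.

## Pipeline and reproducibility

`run_pipeline` chains generate → classify → evaluate → agree → cluster,
writes every table as CSV plus a markdown summary and a JSON manifest
(package version, seed, config hash, row counts), and aborts with the
stage name on failure while preserving earlier artifacts. All randomness
flows from the single run seed through `numpy.random.SeedSequence` spawns
in a fixed order; a rerun with the same manifest is byte-identical. A
post-run audit cross-checks tables (combination-count conservation,
multiplicity vs the all-four pattern, NRI case components vs
false-negative differences). Clustering is skipped with a message when
fewer than two discordant cases exist.

Problem sizes in the shipped tests: default cohorts of 1,281 records (a
few smaller where only mechanics are exercised), 100 generator replicates
for prevalence recovery, 200 random ROC fixtures (n ≤ 60) for the DeLong
oracle, 20–25 Ward instances at n ≤ 12 for the O(n⁴) oracle, and a
10,000-record monotonicity fuzz; the full suite runs in well under a
minute.

## Known limitations

* The SLERPI weight table is configuration pending reconciliation with the
  primary scoring table (see above); all structural constraints are
  enforced at load.
* Cross-sectional only: no longitudinal visits or criteria evolution.
* The EULAR/ACR-2019 transcription omits acute pericarditis (weight 6) and
  maps an unclassified nephritis biopsy to weight 8, both conservative.
* No AUC-difference tests between systems, no multi-category NRI or IDI,
  no bootstrap cluster stability — the comparison design reports CIs,
  binary NRI and a fixed-k clustering only.
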