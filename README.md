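# slecrit

Rule engines and comparison analytics for systemic lupus erythematosus
(SLE) classification criteria.

SLE is clinically heterogeneous, and several competing rule sets exist for
deciding whether a patient "counts" as SLE: the ACR-1997 criteria (≥ 4 of
11 items), the SLICC-2012 criteria (≥ 4 items with at least one clinical
and one immunologic, or biopsy-proven lupus nephritis with ANA or
anti-dsDNA), the EULAR/ACR-2019 criteria (obligatory ANA ≥ 1:80 entry, then
an additive weighted score over ten domains with threshold ≥ 10, counting
only the highest-weighted satisfied item per domain), and SLERPI, a
14-item weighted diagnostic index (score range 0–14, threshold ≥ 7).

`slecrit` is for biostatisticians and rheumatology researchers who validate
or compare such rules. It provides:

* a canonical patient record (tri-state clinical/immunologic feature flags,
  ordered ANA titer, expert reference diagnosis) with CSV I/O and named
  subgroup filters (early disease ≤ 1 year, duration strata, sex, organ
  involvement);
* the four rule engines as pure functions, each driven by an editable YAML
  weight table and exposing both a continuous score and the binary
  classification;
* diagnostic-accuracy statistics: sensitivity/specificity/PPV/NPV/accuracy
  with exact Clopper–Pearson intervals, and ROC AUC via the Mann–Whitney
  estimator with DeLong variance,

  AUC = [#(case > control) + ½·#(ties)] / (n₁·n₀),  Var = S₁₀/n₁ + S₀₁/n₀;

* net reclassification improvement, NRI_total = NRI_events + NRI_non-events,
  with NRI_events = (up − down)/n_cases among cases and
  NRI_non-events = (down − up)/n_controls among controls;
* exact-pattern (UpSet-style) concordance counts, missed-case sets and
  overlaps;
* from-scratch Ward hierarchical clustering (Euclidean distance,
  Lance–Williams updates, deterministic tie-breaking) of discordantly
  classified cases, with per-cluster phenotype summaries;
* a seeded synthetic-cohort generator (Gaussian-copula latent-severity
  model with exact marginal prevalences) so the full pipeline runs without
  patient data.

## Worked example

```python
from slecrit import (CohortConfig, generate, classify_all, evaluate,
                     classification_columns, nri)

cohort = generate(CohortConfig.default(), seed=1)   # 655 cases, 626 controls
class_df = classify_all(cohort)
reports = evaluate(cohort, class_df, subgroups=["overall", "early_disease"])
r = [x for x in reports if x.system == "slerpi" and x.subgroup == "overall"][0]
print(f"SLERPI sensitivity {r.sensitivity.point:.2f}% "
      f"({r.sensitivity.low:.2f}-{r.sensitivity.high:.2f}), AUC {r.auc[0]:.3f}")

cb = classification_columns(class_df)
res = nri(cb["slerpi"], cb["acr1997"], cohort.reference().to_numpy())
print(f"NRI total vs ACR-1997: {res.nri_total:.3f}")
```

prints (seed 1):

```
SLERPI sensitivity 64.27% (60.47-67.95), AUC 0.975
NRI total vs ACR-1997: -0.125
```

The sensitivity is the share of the 655 synthetic cases scoring ≥ 7 under
SLERPI, with its exact binomial CI; the AUC uses the continuous 0–14 score.
On this synthetic profile — which reproduces published marginal feature
prevalences but not the unobserved joint feature structure of real SLE
patients — SLERPI is the most discriminating system by AUC while its fixed
threshold is conservative; see `docs/methods.md` for why synthetic and
real-cohort operating points differ.

The same pipeline is available from the shell:

```sh
slecrit run --out results/run --seed 1
```

which writes the cohort, per-patient classifications, per-subgroup
performance tables, the NRI table, UpSet combination counts, missed-case
tables, Ward linkage/cluster tables, a Newick dendrogram, a markdown
summary, and a reproducibility manifest.

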