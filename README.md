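# lncssn

Single-sample network (SSN) perturbation analysis for discovering
prognostic lncRNA biomarkers from tumor/normal RNA-seq cohorts.

## The problem

Long noncoding RNAs are increasingly recognized as prognostic markers in
cancer, notably hepatocellular carcinoma. Cohort-level differential
expression misses what is *individually* abnormal about each tumor. The
single-sample network approach asks instead: when one tumor sample is added
to a group of normal reference samples, which lncRNAs' correlation
neighbourhoods are disturbed the most?

`lncssn` implements that procedure as a tested, reusable pipeline for
bioinformaticians and statistical-genomics researchers, together with a
synthetic cohort generator that emulates the tumor/normal data structure
(modular coexpression, planted perturbed lncRNAs, survival with censoring)
so that every stage is verifiable without any data download.

## The method

1. **Preprocessing** — genes with zero counts in more than 10% of samples
   are discarded; counts are normalized to log2(CPM+1); differential
   expression (Wilcoxon rank-sum, Benjamini–Hochberg) keeps genes with
   FDR < 0.05 and |log2FC| > 1; symbols shared between the lncRNA and mRNA
   sets are removed.
2. **Single-sample networks** — a reference network `N_r` holds the Pearson
   correlation of every lncRNA–lncRNA and lncRNA–mRNA pair across the
   normal samples. Adding one tumor sample *s* and recomputing gives the
   perturbed network `N_p`, and `N_ssn = |N_r − N_p|` is the ΔPCC matrix of
   sample *s*. Each lncRNA's perturbation score is the row sum

   SD_i = Σ_j ΔD_ij ,

   and the SD vectors of all tumor samples form the perturbation matrix
   *M* (lncRNAs × tumor samples).
3. **Ranking** — each column of *M* is sorted by descending SD; for each
   K ∈ {5, 10, 20, 30} the frequency with which each lncRNA appears in the
   top K positions is counted, the top 5% per K are retained, and the
   intersection over K is the final candidate set.
4. **Survival modelling** — candidates are screened by univariate Cox
   regression on median-dichotomized expression (follow-up truncated at
   5 years = 1825 days); survivors enter a multivariate Cox fit on
   continuous expression, defining the risk score

   RS = Σ_i Exp_i × Coe_i ,

   with the training-set median RS as cut-off. High- vs low-risk groups are
   compared with Kaplan–Meier curves and the log-rank test, and
   discrimination is quantified by an IPCW time-dependent ROC at the 5-year
   horizon. An independence analysis refits the risk group jointly with
   age, sex, weight, grade and stage.
5. **Coexpression** — protein-coding genes correlated with at least one
   biomarker (Pearson r > 0.45, p < 0.01) are exported for external
   enrichment analysis.

## Worked example

```python
from lncssn import (
    SimulationConfig, simulate_cohort, perturbation_matrix,
    candidate_intersection, univariate_cox_screen, split_cohort,
    build_risk_model, risk_score, assign_risk_groups,
    kaplan_meier, logrank_test, time_dependent_roc, truncate_follow_up,
)
from lncssn.preprocess import filter_low_expression, normalize_counts

config = SimulationConfig(n_tumor_samples=200, seed=42)
expr, clinical, truth = simulate_cohort(config)
normalized = normalize_counts(filter_low_expression(expr))

pert = perturbation_matrix(normalized, normalized,
                           normalized.lnc_ids, normalized.mrna_ids)
candidates = candidate_intersection(pert)
print("planted drivers:   ", truth.driver_lnc_ids)
print("final candidates:  ", candidates.final)

tumor = normalized.values[normalized.tumor_sample_ids]
biomarkers, _ = univariate_cox_screen(tumor, clinical, candidates.final)
print("prognostic (p<.05):", biomarkers)

train, test = split_cohort(clinical, seed=0)
model = build_risk_model(tumor[train], clinical.loc[train], biomarkers)
print("coefficients:      ", {g: round(float(b), 3)
                              for g, b in zip(model.lnc_ids, model.coefficients)})

scores = risk_score(model, tumor[test])
groups = assign_risk_groups(scores, model.cutoff)
clin5 = truncate_follow_up(clinical.loc[test])
stat, p = logrank_test(clin5["os_days"], clin5["event"], groups)
roc = time_dependent_roc(scores, clin5["os_days"], clin5["event"])
km = kaplan_meier(clin5["os_days"], clin5["event"], groups)
print(f"testing set: log-rank p = {p:.2g}, 5-year AUC = {roc.auc:.3f}")
for g in ("high", "low"):
    m = km[g][1]
    print(f"  {g}-risk median survival: "
          + (f"{m/365.25:.2f} years" if m < 1e9 else "not reached within 5 years"))
```

Output:

```
planted drivers:    ['LNC0016', 'LNC0030', 'LNC0036']
final candidates:   ['LNC0016', 'LNC0030', 'LNC0036']
prognostic (p<.05): ['LNC0016', 'LNC0030', 'LNC0036']
coefficients:       {'LNC0016': 1.966, 'LNC0030': 0.554, 'LNC0036': 0.857}
testing set: log-rank p = 4.8e-05, 5-year AUC = 0.741
  high-risk median survival: 1.75 years
  low-risk median survival: not reached within 5 years
```

The ranking system recovers exactly the three planted drivers, all three
pass the univariate screen, and the fitted risk score separates the
held-out testing set: high-risk patients reach median survival in under two
years while the low-risk group's curve never crosses 0.5 within the 5-year
follow-up, with an AUC of 0.74 for 5-year survival status.

## Command line

```bash
lncssn run-all --config config.yaml          # full pipeline from a YAML config
lncssn simulate --outdir cohort --seed 1     # synthetic cohort only
lncssn preprocess / ssn / rank / survive / coexpress   # stage by stage
```

Every run writes its artifacts (expression/clinical TSVs, DE table,
perturbation matrix, candidate JSON, screening and independence tables,
risk model) plus a `manifest.json` with parameter values, stage seeds and
SHA-256 digests of every file.

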