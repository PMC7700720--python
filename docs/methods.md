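# Methods

This note documents the models, conventions and design choices behind
`lncssn`: what each stage computes, what the synthetic generator does and
does not emulate, and where genuinely open decisions were settled.

## Single-sample perturbation networks

For reference samples (normals) the reference network `N_r` is the matrix
of Pearson correlations between every lncRNA and every partner gene
(partners = all lncRNAs and all mRNAs in the panel). For a tumor sample
*s*, the perturbed network `N_p` is recomputed over the reference samples
plus *s*, and the sample's ΔPCC matrix is `|N_r − N_p|`. The perturbation
score of lncRNA *i* in sample *s* is the row sum SD_i = Σ_j ΔD_ij; SD
vectors over all tumor samples form the perturbation matrix *M*.

Conventions:

- **Complete edge set.** All lncRNA–lncRNA and lncRNA–mRNA pairs
  contribute; no significance pruning of edges. lncRNA–lncRNA edges are
  counted in both endpoint rows (each lncRNA sums *all* its incident
  edges).
- **Self pairs** are fixed at correlation 1 in both networks and therefore
  contribute exactly 0 to every SD; they are explicitly zeroed so the
  invariant holds regardless of floating-point detail.
- **Constant genes** have no defined correlation; their entries are 0 by
  convention, contributing no perturbation signal rather than NaNs.
- **Bounds.** Every ΔPCC entry lies in [0, 2] and SD_i in [0, 2(P−1)];
  these are asserted as properties in the test suite, and the vectorized
  implementation is checked against a naive double-loop oracle to 1e-10
  on randomized small instances.
- An optional **z-score mode** divides each ΔPCC by the large-sample
  standard error (1 − r_ref²)/(n_ref − 1), for comparability with
  perturbation tests that normalize edge shifts. The plain |ΔPCC| mode is
  the default and the one used everywhere else in the package.

Each perturbed network is recomputed in full (a rank-one update would be
possible but the full recomputation is simple, exactly matches the
contract, and is far from the bottleneck at the problem sizes used).

## Ranking system

Each column of *M* is sorted by descending SD — high SD means most
perturbed — with ties broken by lexicographic lncRNA id so runs are
deterministic. For each window size K the frequency of each lncRNA in the
top K rows is counted; the round-to-nearest(5% × L) highest-frequency
lncRNAs are retained per K (948→47, 956→48; boundary ties again
lexicographic); the final candidates are the intersection over
K ∈ {5, 10, 20, 30}. Round-to-nearest keeps published panel sizes (5% of
956 = 47.8 → 48) while a fraction that rounds to zero is an explicit
error. K values larger than the available panel are dropped by the
pipeline with a warning. An empty intersection is a warning, not an
error — downstream stages handle empty candidate sets.

## Survival modelling

- **Follow-up truncation.** All survival fits administratively censor
  follow-up at the 5-year horizon (1825 days) first.
- **Univariate screen.** Each candidate is dichotomized at its median
  expression (high = value ≥ median, so an odd cohort splits
  (n+1)/2 high / (n−1)/2 low) and fitted as a single binary covariate;
  candidates with Wald p < 0.05 survive. Group-based screening and a
  continuous-expression risk model are deliberately different readings of
  the same data: hazard ratios for "high vs low" groups are easier to
  report, while the risk score needs per-sample granularity.
- **Cox fits** maximize the Efron partial likelihood via lifelines
  (Newton-type iteration). Efron tie handling matters because survival
  times are recorded in whole days. A constant covariate or fewer events
  than covariates is an error; perfect separation yields a non-converged
  model that the screen excludes with a warning. Fits are verified in the
  tests against a brute-force grid maximization of a hand-written partial
  likelihood and by parameter recovery on simulated exponential hazards.
- **Risk score.** RS = Σ Exp_i × Coe_i with the multivariate coefficients;
  the training-set median RS is the cut-off, and high risk ⇔ RS ≥ cut-off.
  The identical model and cut-off are applied to the testing and entire
  sets.
- **KM / log-rank.** Product-limit curves per risk group; the median is the
  smallest time with S(t) ≤ 0.5 (infinite when not reached). The log-rank
  statistic is the standard two-group chi-square with 1 df, checked against
  a hand-tabulated 6-subject example and against the Cox Wald chi-square on
  large samples.
- **Time-dependent ROC.** Cumulative-case / dynamic-control at the horizon
  with inverse-probability-of-censoring weights: cases (event by the
  horizon) weigh 1/G(T−), controls (event-free past the horizon) weigh
  1/G(horizon−), where G is the Kaplan–Meier estimate of the censoring
  survival function. The left limit at the horizon matters: with
  administrative truncation exactly at the horizon the right-continuous G
  drops to 0 there even though controls were genuinely observed. Tied
  scores count 1/2, so with no censoring the AUC is exactly the
  Mann–Whitney statistic; a constant marker scores 0.5 by convention. The
  implementation is cross-checked in the tests against scikit-survival's
  independent IPCW estimator.
- **Independence analysis.** The risk group is refitted jointly with age,
  sex, weight, grade and stage, reporting univariate and multivariate HR,
  95% CI and p per variable. Contrasts are risk high vs low, sex male vs
  female, grade I+II vs III+IV and stage I+III vs II+IV — the stage
  contrast is unusual but reproduces the reporting convention this package
  mirrors.
- **Cohort split.** A seeded uniform permutation assigns ⌈n/2⌉ patients to
  training and the rest to testing (307 → 154/153).

## Differential expression stage

The DE stage exists to select the gene panel, not to innovate: genes with
zero counts in more than 10% of samples (strict) are discarded *before*
normalization (the filter targets raw detectability); normalization is
log2(CPM+1); the two-group test is a Wilcoxon rank-sum on normalized
values with BH adjustment; thresholds FDR < 0.05 and |log2FC| > 1 are both
strict. The stage is pluggable — an externally computed DE table in the
same schema can replace it, which also permits exact replication of any
other DE method's panel — and the pipeline's `de_filter` switch can bypass
the DE gate entirely so the whole detected panel enters the network (the
right choice when the tumor signal is relational rather than a mean
shift). Symbols shared between the DE-lncRNA and DE-mRNA
sets are removed from both; within a set, duplicate symbols keep the first
occurrence in gene order.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
not realistic RNA-seq reads:

- **Latent coexpression layer.** mRNAs form modules of
  `n_partners_per_driver` genes; every gene in a module, and every lncRNA
  (each attached to one module), loads √ρ on the module factor, giving
  pairwise correlation ρ = `baseline_corr` within a module. Gaussian
  latents are mapped to negative-binomial counts by a copula
  (count = NB-quantile of Φ(z), var = μ + `nb_dispersion`·μ²), so Pearson
  structure on the log scale is the controlled quantity. Per-gene means are
  log-normal around `mean_log_expression`.
- **Planted perturbation.** In tumor samples each driver lncRNA's factor
  loading is attenuated so its correlation with partners shifts by
  `perturbation_strength` (or sign-flipped, configurable), *and* its
  latent level is displaced by `driver_displacement_scale ×
  perturbation_strength` latent SDs. The displacement is integral to the
  perturbation model: a sample-level |ΔPCC| signal requires the added
  sample to deviate from the reference joint distribution, and a lncRNA
  whose regulatory coupling is lost plausibly leaves its homeostatic
  range. Loading rewiring alone (a ~0.6/n_ref per-edge correlation shift)
  is numerically invisible against per-edge sampling noise at realistic
  reference sizes. Because every lncRNA has the same attachment
  distribution, drivers are *exactly exchangeable* with background
  lncRNAs at perturbation strength 0, making the null case sharp.
- **Survival.** Tumor hazards are exponential with log-hazard =
  log(`baseline_hazard`) + Σ β_d · z_d over standardized driver log2
  expression; censoring is an independent exponential. Defaults
  (`baseline_hazard` 4e-4/day, `censoring_rate` 2.4e-4/day, β = 0.7 per
  driver) give a median OS near 2–4 years and ≈40% censoring, typical of a
  hepatocellular-carcinoma cohort. Times are rounded to whole days
  (creating realistic ties), minimum 1 day.
- **Nuisance covariates.** Age, sex, weight, grade and stage are drawn
  independently of survival, so the independence analysis has a known
  ground truth: only the risk score should be significant.
- **Optional background fold changes.** `background_log2fc_sd` > 0 gives
  non-driver genes tumor/reference mean shifts so the DE filter has a
  realistic substrate; the default is 0, keeping the planted perturbation
  the only tumor/normal difference. With background fold changes enabled,
  strongly shifted background genes legitimately compete with drivers for
  perturbation rank — exactly as strongly differential genes would in real
  data — so driver-recovery guarantees are stated for the default
  conditions.
- One `numpy` generator stream, seeded from the config, governs all
  randomness; identical configs are byte-identical.

What passing tests on this generator show: the network arithmetic, ranking
logic and survival machinery behave correctly on data with known truth.
What they do not show: robustness to library-size artifacts, batch
effects, non-NB noise, or biologically structured censoring — none of
which the generator emulates.

## Default problem sizes

Cohorts of 50 reference / 100–200 tumor samples over 60 lncRNAs and 200
mRNAs with 3 planted drivers are the package's standard study conditions;
they preserve every structural feature of the full-scale analysis (which
the implementation handles unchanged) while keeping any simulation a
matter of seconds. The acceptance script reports, for each quantity, the
problem size it was computed at.

## Known limitations

- The DE stage is a rank-sum test, not a count-model test; panels will
  differ from negative-binomial DE methods at the margins.
- The perturbation score aggregates |ΔPCC| without per-edge significance
  testing; the z-score mode is provided but not the default.
- Exponential survival and censoring are convenient, not flexible; no
  competing risks, no proportional-hazards diagnostics.
- The printed stage contrast (I+III vs II+IV) in the independence report
  mirrors an external reporting convention rather than a clinical
  grouping.
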