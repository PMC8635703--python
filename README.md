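# resilnet

Resilient functioning to stress, quantified as regression residuals, and
psychological network analysis of general self-efficacy — as one tested,
reproducible pipeline.

## The scientific problem

Resilience research increasingly defines *resilient functioning* not as a
trait score but as an outcome relative to adversity: a person functions
resiliently when their mental health is better than what their stressor
history predicts. Given a cohort assessed with

- a **Daily Hassles checklist** (58 minor stressors; 0–7 frequency and 1–5
  severity),
- a **Life Events checklist** (27 major stressors; 0–5 lifetime severity),
- the **WHO-5** well-being index (5 items, 0–5),
- the **BSI-18** symptom inventory (18 items, 1–5; somatization, depression
  and anxiety subscales), and
- the **General Self-Efficacy scale** (GSE; 10 ordinal items, 1–4),

the pipeline

1. builds four higher-is-healthier outcomes (WHO-5 sum, three inverted
   BSI-18 subscale sums), rank-inverse-normal transforms and z-standardizes
   them, and residualizes them on age and gender;
2. fits a **one-component partial least squares regression (PLSR,
   SIMPLS)** of the outcome block `Y` (n×4) on the stressor block `X`
   (n×143) and validates its explained variance against permuted refits;
3. defines each subject's **resilient-functioning score** as the mean of
   their four PLSR residuals — positive means healthier than predicted —
   and splits the sample at 0 into *high* (> 0) and *low* (≤ 0) groups;
4. estimates, per group, a **regularized partial-correlation network** of
   the 10 GSE items: pairwise polychoric correlations (two-step maximum
   likelihood for ordinal data), positive-definite repair if needed,
   graphical lasso over a 100-point penalty path with **EBIC (γ = 0.5)**
   model selection, with thresholded / unthresholded / unregularized
   variants all written out;
5. compares **global connectivity** between groups — average node strength
   `mean_i Σ_j |w_ij|`, average expected influence `mean_i Σ_j w_ij`, and
   average shortest path length with edge distance `1/|w_ij|` — and runs a
   permutation **network comparison test** of global strength
   (Σ upper-triangle |w_ij|), re-estimating both networks under shuffled
   group labels each iteration;
6. reports descriptive group contrasts (Welch t with Cohen's d; per-item
   Wilcoxon rank-sum tests, Bonferroni-corrected).

Because the original cohort is available only on request, the package ships
a first-class **synthetic cohort generator** with full ground truth: a
latent stress factor drives all stressor items, latent health is
`stress_effect·stress + offset`, and each subject's GSE items are
thresholded draws from a latent Gaussian graphical model whose precision
matrix depends on whether their resilience offset is above the median
(chain graphs with edge partial correlations 0.35 vs 0.15 by default).
Every downstream stage is therefore testable against known truth.

## Worked example

```python
from resilnet import (SyntheticConfig, generate_cohort, preprocess_design,
                      ResilienceScorer, EBICGraphicalLasso,
                      connectivity_metrics, nct_global_strength)

cohort = generate_cohort(SyntheticConfig(seed=1))       # n = 875, 73% women
design = preprocess_design(cohort)                      # Y: 875x4, X: 875x143

scorer = ResilienceScorer().fit(design.X, design.Y)
print(scorer.r2_, scorer.n_high_, scorer.n_low_)
# 0.14014736832565666 452 423

high = scorer.group_ == "high"
for label, mask in [("high", high), ("low", ~high)]:
    net = EBICGraphicalLasso(threshold=False).fit(cohort.gse[mask])
    m = connectivity_metrics(net.weights_)
    print(label, round(m.avg_strength, 3), round(m.avg_shortest_path_length, 2))
# high 0.475 15.43
# low 0.137 29.72

res = nct_global_strength(cohort.gse[high], cohort.gse[~high],
                          n_iterations=1000, random_state=0)
print(round(res.observed_diff, 3), res.p_value)
# 1.608 0.000999000999000999
```

The PLSR explains ~14% of outcome variance (far above its permutation
null), splits the cohort into 452 high / 423 low resilient-functioning
subjects, and the high group's self-efficacy network is several times as
strongly connected — with correspondingly shorter paths — than the low
group's, a difference the permutation test calls significant on this
synthetic cohort.

The same chain runs from the shell:

```bash
resilnet run-all --out run1 --seed 1
resilnet simulate --out cohort_csvs --seed 3 --n 875
resilnet compare --items-a a/gse.csv --items-b b/gse.csv --out nct.json
```

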