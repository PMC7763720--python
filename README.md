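# brsrisk

Risk stratification for Brugada syndrome (BrS) — an inherited arrhythmogenic
condition whose carriers face elevated risk of spontaneous ventricular
tachycardia / ventricular fibrillation (VT/VF) — from routine clinical and
ECG variables. The package is aimed at cardiology researchers who want to go
beyond additive logistic models: its core idea is to extract **latent
variables** from the *interrelations* between clinical risk factors and ECG
measurements by **nonnegative matrix factorization (NMF)** and feed them to
the logistic risk model, improving discrimination when the outcome depends on
clinical × ECG interactions that an additive model cannot represent.

## The model

For each of *n* patients, clinical flags *c* ∈ {initial spontaneous type 1
pattern, syncope, atrial fibrillation} and min–max-scaled ECG variables
*e* ∈ {QRS duration, QTc interval} form an interrelation matrix
**V** ∈ [0,1]^(n×6) with columns V₍c,e₎ = c·ẽ. NMF factorizes

  **V** ≈ **W H**,  W ≥ 0 (n × d), H ≥ 0 (d × 6),

minimizing ‖V − WH‖_F by Lee–Seung multiplicative updates with random
restarts. The *d* columns of **W** are per-patient latent variables, appended
to the base risk variables (syncope, AF, QRS, QTc) in an unpenalized
logistic regression fitted by IRLS:

  logit P(VT/VF) = β₀ + β᷀ᵀx_base + γᵀW.

Performance is scored by stratified 2-fold cross-validation (precision,
recall, F1 macro-averaged over the outcome classes at threshold 0.5, and
threshold-free AUC), sweeping d = 0, 2, …, 6; d = 0 is exactly the plain
logistic baseline. Inside cross-validation the factorization is fitted on
the training fold only and held-out patients are embedded by solving the
convex W-subproblem against the frozen loadings **H** — no information flows
across the fold boundary.

Supporting tools: group-comparison descriptives (Fisher's exact test,
Wilcoxon rank-sum, Kruskal–Wallis), univariate odds ratios with Woolf/Wald
95% CIs (closed-form from 2×2 tables, and as logistic fits), ROC analysis
with DeLong or bootstrap AUC CIs and Youden-index optimal cutoffs, Bazett
heart-rate correction (QTc = QT/√RR), and a synthetic cohort generator with
calibrated prevalence, planted marginal odds ratios, and an optional planted
low-rank latent structure.

## Worked example

A deterministic 149-patient cohort fixture reproduces a published BrS
cohort's binary contingency counts (32 VT/VF cases / 117 controls; syncope
22 vs 43; AF 5 vs 5; …). Univariate odds ratios computed from it:

```python
from brsrisk import fixture_table1_cohort, univariate_or_table

cohort = fixture_table1_cohort()
for row in univariate_or_table(cohort, ["syncope", "af", "sex"]):
    o = row.result
    print(f"{row.variable:8s} OR {o.odds_ratio:.2f} "
          f"({o.ci_low:.2f}-{o.ci_high:.2f}) p={o.p_value:.3f}")
```

prints

```
syncope  OR 3.79 (1.64-8.74) p=0.002
af       OR 4.15 (1.12-15.36) p=0.033
sex      OR 0.29 (0.06-1.30) p=0.105
```

i.e. syncope multiplies the odds of spontaneous VT/VF by ≈3.8 and AF by
≈4.1, while female sex (male as reference) shows no significant association.
On a synthetic cohort with a planted clinical×ECG interaction the latent
features raise the cross-validated AUC over the additive baseline:

```bash
brsrisk simulate --n 400 --seed 3 --latent --out cohort.csv
brsrisk evaluate --cohort cohort.csv --d-values 0,3 --seed 3
```

```
d       precision       recall  f1      auc
0       0.8646  0.6400  0.6733  0.7461
3       0.8354  0.7402  0.7723  0.8583
```

The CLI also exposes `brsrisk table1` (group comparison), `brsrisk assoc`
(odds-ratio table) and `brsrisk roc` (AUC, CI and Youden cutoff).

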