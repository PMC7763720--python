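# Methods

## Problem and data model

One row per patient: demographics (age, sex), clinical flags (syncope,
atrial fibrillation [AF], initial spontaneous type 1 ECG pattern, programmed
ventricular stimulation [PVS] performed/positive, ICD), ECG measurements
(QRS duration in ms; QT and RR from which QTc = QT/√RR by Bazett's
correction, or QTc supplied directly — a supplied value wins over a derived
one, with a logged warning), and the binary outcome, spontaneous VT/VF.
Record invariants: QRS ∈ (40, 300) ms, QTc ∈ (250, 700) ms, age < 120,
PVS-positivity defined exactly when PVS was performed. CSV I/O is
comma-separated UTF-8 with booleans as 0/1 and absent optionals as empty
cells; `read_cohort ∘ write_cohort` is the identity on valid cohorts.
Records missing a variable required by a particular analysis are excluded
from that analysis only, with a logged count.

## Descriptive comparisons

Binary variables are compared between the VT/VF and non-VT/VF groups as
count (percent, rounded half-up) with the two-sided Fisher's exact test
under the probability-mass rule (sum of hypergeometric probabilities not
exceeding the observed table's); continuous variables as median (q1–q3)
with the Wilcoxon rank-sum test — exact enumeration when the pooled sample
has ≤ 12 values without ties, otherwise the tie-corrected normal
approximation with continuity correction. Kruskal–Wallis (tie-corrected H,
χ² reference with k−1 df) covers ≥ 2 groups; on fully tied data we define
H = 0, p = 1 (the 0/0 limit of the tie correction). Quartiles use linear
interpolation between order statistics (numpy's default, the "type 7"
convention), configurable; no convention is canonical for this kind of
table, and type 7 is the most widespread.

## Univariate association

For a 2×2 exposure × outcome table with cells a, b, c, d the odds ratio is
the cross-product (a·d)/(b·c) with the Woolf (log-scale Wald) CI
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) and a two-sided Wald p. Zero cells raise
an error naming the cell; the Haldane–Anscombe +0.5 correction is available
behind a flag, never silently. The logistic route fits the same model by
maximum likelihood; on an all-positive 2×2 table the two routes agree to
numerical precision, which the test suite exploits as an exact oracle.

Logistic regression is unpenalized IRLS (Newton–Raphson on the
log-likelihood) with zero-initialized coefficients, convergence when the
score's max-norm falls below 1e-8 (max 100 iterations), and covariance from
the inverse observed information. Plain Newton steps can overshoot and
oscillate on strong signals even when the MLE exists, so each step is
halved until the log-likelihood does not decrease. Complete or
quasi-complete separation is flagged when any coefficient passes 15 on the
logit scale — a magnitude no bounded design column of a real fit here
produces (all design columns are standardized or 0/1); a singular
information matrix raises a rank error. Sex is coded female = 1 with male
as reference; continuous predictors are per unit (per year, per ms).

## ROC and optimal cutoffs

Thresholds are the midpoints between consecutive distinct scores plus ∓∞
sentinels, calling a patient positive when score ≥ threshold; with
integer-valued ECG measurements this yields the half-unit cutoffs familiar
from clinical tables. The trapezoidal area under the resulting curve equals
the Mann–Whitney statistic with ties counted 1/2, exactly — a property the
suite asserts on random tied instances. The Youden-optimal cutoff maximizes
sensitivity + specificity − 1, ties broken toward the smallest qualifying
cutoff (deterministic; the choice is arbitrary and configurable in
analysis code built on the library). AUC CIs: DeLong placement-value
variance with a normal interval by default (deterministic); a
class-stratified percentile bootstrap with a fixed seed as the alternative
and as the automatic fallback when a class has fewer than 2 members.
Intervals are clipped to [0, 1].

## NMF core

Frobenius-norm NMF by multiplicative updates
H ← H·(WᵀV)/(WᵀWH + ε), W ← W·(VHᵀ)/(WHHᵀ + ε), ε = 1e-10, which never
increase the objective (asserted per iteration, slack 1e-10 for round-off).
Entries initialize as Uniform(0,1)·√(mean(V)/d); restart k of n_restarts
(default 5) uses seed seed+k, making results bit-reproducible; the best
final loss wins. Stopping: relative objective decrease < 1e-6 (default) or
500 iterations. The diagonal scale indeterminacy is resolved by giving each
row of H unit max and rescaling W inversely (the product is unchanged to
round-off). An all-zero V returns zero factors with zero loss; d exceeding
both dimensions is permitted (over-complete) but logged. Held-out
projection freezes H and runs the W-update alone — the convex subproblem —
so new rows are embedded without touching the training loadings.

## The latent-risk pipeline

The interrelation matrix V has one column per (clinical flag, ECG variable)
pair holding flag × min–max-scaled ECG value — 3 clinical × 2 ECG = 6
columns by default, which also bounds the useful latent dimension at 6. A
`raw_features` mode (flags and scaled ECG side by side, 5 columns) is
retained as the alternative construction. The design matrix is
[intercept | syncope, AF, standardized QRS, standardized QTc | d latent
columns]; the latent columns are standardized as well, because the unit-max
H convention leaves W on an arbitrary compressed scale — standardization is
an affine reparametrization (fitted probabilities and AUC are unchanged)
that keeps coefficient magnitudes interpretable and the separation guard
meaningful.

Cross-validation is stratified (per-class shuffle, round-robin deal),
2-fold by default, with min–max scaling, standardization statistics and NMF
loadings all computed on the training fold only; held-out rows are embedded
by projection. The joint (all-rows) factorization is available behind
`joint_nmf=True` for comparison but leaks feature information across folds
and is not the default. d = 0 skips NMF entirely and is numerically
identical to plain logistic CV on the same folds. Precision, recall and F1
are computed at probability threshold 0.5 and macro-averaged over the two
outcome classes by default (weighted and positive-class averaging are
options); with ~21% prevalence, positive-class-only metrics would sit far
below the macro values a well-calibrated baseline produces. AUC is
threshold-free. Folds hitting separation are flagged and excluded from the
means with a warning. A d-sweep shares one fold assignment across all d so
comparisons are paired; the CLI offers `--repeats` to average grids over
repeated splits.

## Synthetic cohorts

The generator emulates the study conditions of a moderate single-centre BrS
cohort: n = 149, 84% male, outcome prevalence 21%, syncope ≈ 44%, AF ≈ 7%,
initial type 1 ≈ 53%, PVS performed ≈ 30% (64% positive), age ≈ median 50
(IQR 38–61), QRS ~ N(103, 11²) ms clipped to (60, 200), QTc ~ N(412, 28²)
ms clipped to (320, 560) — moments bracketing the observed medians/IQRs,
synthetic rather than estimates. RR ~ N(0.9, 0.12²) s and QT = QTc·√RR keep
the Bazett relation internally consistent.

Outcomes are logistic with planted *univariate* odds ratios 3.79 (syncope),
4.15 (AF), 1.03/ms (QRS), 1.02/ms (QTc). Because marginal odds ratios are
attenuated relative to joint-model coefficients (non-collapsibility), the
conditional coefficients are inflated by the logistic-normal factor
√(1 + c²s²) — s² the residual linear-predictor variance of the other
covariates, c = 1/1.6 from the conventional 1.6–1.8 range, fixed by
calibrating the generator against its own large-n univariate estimates — so
the population univariate estimates land on the stated targets. The
intercept is then solved by bisection (tolerance 1e-4 on the mean predicted
probability) to hit the target prevalence exactly in expectation;
infeasible targets raise a calibration error.

The optional latent plant draws per-patient nonnegative factors
U ~ Uniform(0,1)^(n×d_true) and column-normalized Uniform(0,1) loadings L,
shifting both the clinical-propensity logits and the ECG means
(loading_scale = 0.5 of each variable's spread; ECG residual noise 0.7 sd)
— a recoverable low-rank structure in the interrelation matrix. The outcome
logit additionally gains outcome_scale = 10 log-odds per unit of the
loadings-weighted, mean-centered clinical × ECG product score; weights are
the loadings' overlaps scaled by each flag's variance so the rare AF flag
does not dominate. Centering keeps this term near-orthogonal to the main
effects: the additive baseline stays at its own discrimination level
(cross-validated AUC ≈ 0.75 at n = 600) while the latent-feature model
gains ≈ 0.05 AUC — the same regime, baseline ≈ 0.71 improving to ≈ 0.80,
reported for real BrS cohorts. These magnitudes were fixed once at design
time and are not tuned per experiment.

What the generator does *not* emulate: between-site heterogeneity,
correlated missingness, measurement drift, non-logistic outcome mechanisms,
or ECG waveform morphology. Passing tests therefore demonstrate internal
correctness and the qualitative value of latent interaction features under
the stated generative assumptions — not clinical performance on real
cohorts.

## Problem sizes and determinism

The test suite and the acceptance script use: the deterministic 149-patient
count-exact fixture for the odds-ratio reproductions; 500 random 2×2 tables
for the logistic/cross-product oracle equivalence; 200 random tied
instances for the ROC identities; 20×6 planted matrices for NMF recovery;
and 20 synthetic cohorts of n = 600 (2-fold CV) for the latent-gain and
permuted-label-null properties, with parameter recovery at n = 10,000.
Every stochastic step takes an explicit seed; identical seeds give
identical bytes.

## Known limitations

Multiplicative updates converge slowly near zero entries, so very tight
reconstruction targets need generous iteration budgets (the recovery tests
use max_iter in the thousands with tol ≤ 1e-10). The d-sweep's
"loss nonincreasing in d" holds to a small absolute slack (1e-6) because
exact-recovery fits at different d bottom out at round-off-scale losses in
a non-monotone order. DeLong intervals are asymptotic and can degenerate at
AUC = 1; the bootstrap fallback covers tiny classes. The separation
threshold (|coefficient| > 15) is a heuristic for divergence, appropriate
because all design columns are standardized or 0/1. Quasi-separation is a
real phenomenon in small folds with strong effects; affected folds are
excluded from CV means rather than imputed.
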