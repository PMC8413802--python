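# Methods

## The model

`epiiprofiles` profiles survey respondents by patterns of endorsed
pandemic-related experiences. The measurement model is a latent class
model (finite mixture) for J dichotomous indicators: respondent i
belongs to one of K unobserved classes, class k has weight
π_k (Σ π_k = 1), and endorses item j with probability ρ_jk,
independently across items given class (local independence):

    P(y_i) = Σ_k π_k Π_j ρ_jk^{y_ij} (1 − ρ_jk)^{1 − y_ij}

Posterior membership probabilities τ_ik follow by Bayes' rule; modal
assignment takes the argmax per respondent. Local independence is an
assumption, not a finding: correlated residuals within a class (e.g.,
parallel child-related items) inflate the apparent number of classes.

## Estimation

Maximum likelihood by EM with multiple random starts. Defaults: 50
starts (π from a flat Dirichlet, ρ uniform on [0.1, 0.9]), absolute
log-likelihood tolerance 1e-6, at most 1000 iterations. One master seed
spawns per-start streams, so fits are bit-reproducible. Duplicate
response patterns are collapsed before iterating (an exact
reformulation; pattern counts are sufficient). All per-pattern work is
in log space with log-sum-exp stabilization; when J is small enough
that the per-pattern log-density cannot underflow, an equivalent
linear-space E-step is used for speed.

Numerical choices: ρ is clamped to [1e-5, 1 − 1e-5] at every M-step
(clamp events are counted and reported); class weights get a 1e-10
floor so a collapsing class stays finite; exact posterior ties break
toward the lowest class index and are flagged. A solution is treated as
a trustworthy maximum when at least two starts reach the best
log-likelihood within 1e-4 ("replication"); enumeration stops when a
candidate fails this, the operational version of "a unique solution
could not be determined". Because mixtures are identified only up to
label permutation, estimates are aligned to a reference by optimal
assignment (Hungarian method) on the L1 distance between ρ columns.

## Screening and scoring

EPII raw codes collapse as yes-me/yes-other → 1 and no/not-applicable
→ 0. The rare opt-out response also maps to 0 (conservative:
not-endorsed); opt-out cells are counted per run. Psychosocial scales
(PSS, PHQ-9, GAD-7, PC-PTSD-5, Duke-UNC SSQ) are item sums after
within-respondent mean imputation of opt-outs; screens use the standard
cutoffs PHQ-9 ≥ 15, GAD-7 ≥ 15, PC-PTSD-5 ≥ 3 (one published table row
labels the anxiety screen "≤ 15"; it is implemented as ≥ 15, treating
the printed direction as a typographical inversion).

Indicator screening drops items with base rate strictly below 5%
("<5%" is adopted over the alternative "≤5%" phrasing; the 16 published
exclusions satisfy both), then retains items whose Spearman correlation
with the PSS total is significantly positive. The test is one-sided
positive at α = 0.05 by default — the published item table leaves a
negative correlation of −.087 unstarred while starring positive values
of .08, which identifies the criterion as positive-only — and is
configurable to two-sided. P-values use the large-sample t
approximation on midranks; below N = 30 an exact permutation test is
used. No multiplicity correction is applied at this stage, matching
the source procedure.

## Model selection battery

For each K: BIC, SABIC, CAIC (Bozdogan) and AWE (Banfield–Raftery) on
the −2LL + penalty scale (formulas in `selection.py`); adjacent-model
Bayes factors BF = exp(SIC_A − SIC_B) with SIC = −BIC/2 and
correct-model probabilities cmP as normalized evidence weights, both in
log space; relative entropy E = 1 − Σ_i Σ_k (−τ_ik ln τ_ik)/(N ln K);
and the assigned-class-by-class mean posterior matrix. The selected
model is the smallest-BIC candidate, with BF and cmP as corroboration.

Univariate entropy measures one item's contribution to separation: the
single-item posterior τ_k(y) ∝ π_k ρ_jk^y (1 − ρ_jk)^{1−y} is averaged
over the model-implied distribution of y_j, e_j = 1 − E_y[H(τ(y))]/ln K.
The averaging convention behind the original software's column is
undocumented; this definition is declared here and reproduces the
published column's ordering closely (the childcare, teaching and
work-exposure items dominate).

Testing K against K−1 uses a parametric bootstrap likelihood-ratio
test: the naive LR statistic 2(LL_K − LL_{K−1}) is referred to a null
distribution simulated from the fitted K−1 model, with the add-one
p-value convention (1 + #{LR_b ≥ LR_obs})/(B + 1). The VLMR test used
in the original analysis relies on reference-distribution
approximations that are not reproducible from the publication, so the
bootstrap is the supported test and the naive statistic is reported for
transparency. Bootstrap refits reuse the parent solutions as warm
starts plus one random start, tolerate a relaxed convergence tolerance
(1e-4), and accept the best available solution when the iteration cap
is hit (non-converged refits are counted) — a lower bound on a refit
log-likelihood perturbs the simulated null far less than it costs to
chase flat-ridge convergence.

The published CAIC and AWE columns imply per-parameter penalties
(≈3.81 and ≈4.31 at N = 652) matching neither the cited formulas nor
sample-size-adjusted variants, and the published BF/cmP values imply
adjacent BIC differences about a tenth of those printed in the same
table; these columns are therefore computed by the standard formulas
here and not expected to reproduce the printed values. Recomputing BIC
and SABIC from the printed (LL, d, N) reproduces five of the seven
printed rows to ±0.02; the three-class row (both) and the seven-class
BIC disagree by 0.19–0.25 and are internally inconsistent with their
own printed log-likelihoods (the seven-class SABIC from the same LL
matches to 0.005), i.e., misprints in the source table.

## Distal outcomes: 3-step correction

Classes are compared on outcomes excluded from the measurement model.
Step 1 fits the LCA; step 2 assigns modally; step 3 treats the
assignment as an error-prone class indicator with misclassification
rates q_ks = Σ_i τ_ik 1[W_i = s]/Σ_i τ_ik fixed, and maximizes
Σ_i log Σ_k π̂_k q_{k,W_i} f(y_i | θ_k) over the outcome parameters
only. Continuous outcomes use class-specific normals with unequal
variances (means and variances free per class); categorical outcomes
use class-specific category probabilities. Standard errors come from
the observed information (numerical Hessian on means/log-variances or
baseline-category logits), so they ignore step-1 uncertainty, as in the
source procedures. Overall equality is a Wald chi-square ((K−1) df for
means, (K−1)(C−1) for categorical); pairwise contrasts are Wald tests
(z on mean differences; chi-square on log-odds differences) at the
Bonferroni-adjusted level α/(K(K−1)/2) — 0.005 for five classes at
family α = 0.05. With one-hot posteriors Q is the identity and both
procedures reduce exactly to naive per-assigned-class summaries. The
correction is reliable only with adequate separation; below relative
entropy 0.60 a warning is raised (a warning, not a stop: the published
analysis applied it at entropy 0.868).

## Synthetic survey generator

The generator emulates the published study population so every stage is
testable without the (unshared) respondent data. Defaults: N = 652;
five classes at the published proportions 18.1/14.4/31.4/17.3/18.7%
(printed values sum to 99.9% and are renormalized); the 38 indicators
drawn Bernoulli(ρ_jk) from the published conditional probabilities
(printed to two decimals — generator fidelity beyond that precision is
not claimed); the remaining 54 items class-independent at their
published base rates; binary sociodemographics and screens at the
published class-conditional rates. Endorsements split 80/20 into
yes-me/yes-other (unreported in the source; the pipeline collapses them
anyway) and non-endorsements 85/15 into no/not-applicable; household
items are always coded yes-me.

Scale items are generated totals-first: a class-conditional normal
total is drawn, rounded, clipped, and allocated uniformly across items
within their ranges (only totals enter the analysis). For the three
screen-bearing scales the class-conditional means invert the normal
exceedance at the published screen rates (SD 5 for PHQ-9/GAD-7, 1.5
for PC-PTSD-5, with a half-point continuity correction), so scored
screens approximately reproduce those rates. The perceived-stress
means (20, 22, 19, 14, 12; SD 6) and social-support means
(18, 15, 16, 21, 22; SD 4) are package choices — no class-conditional
values are published — placing high stress and low support in the
three high-risk classes so that screening and distal comparisons
behave as in the source population.

What the generator does not emulate: violations of local independence,
realistic joint sociodemographic distributions, missingness beyond rare
opt-outs, and item-level response styles. Passing recovery tests
therefore demonstrates correctness of the estimators under the model,
not robustness to real-data misspecification.

## Problem sizes used in the test suite

Recovery studies fit K = 1..7 with 50 starts to n = 2000 generated
respondents (plus a scaled-down n = 500 run); under these conditions
BIC selects the generating K = 5, relative entropy lands near 0.91
(above the published 0.868 — real data are noisier than their own
fitted model), and aligned class shares sit within about two points of
the generators. The maximal absolute error of the 190 recovered ρ
values is dominated by binomial sampling noise: with the smallest class
near 290 respondents the typical worst cell is 0.06–0.10 at n = 2000.
Bootstrap-LRT calibration uses a deliberately small instance (N = 100,
J = 4, B = 99, 200 repetitions) where the test's type-I error can be
measured affordably. The classification-error-correction study uses
the published depression-screen profile at n = 2000.

## Known limitations

* Covariates in the measurement model, ordinal/continuous indicators,
  multilevel extensions and the BCH weighting variant are out of scope.
* Step-3 standard errors condition on the step-1 solution.
* The bootstrap LRT's p-value resolution is 1/(B+1).
* PSS reverse-scoring is not modeled; the total-sum contract is taken
  as given.
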