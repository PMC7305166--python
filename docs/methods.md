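# Methods

`ipfpvol` predicts infrapatellar fat pad (IPFP) volume — the adipose body
behind the patellar tendon, measured in mm³ on knee MRI — from per-subject
tabular predictors: the three main osteoarthritis risk factors (age,
gender, BMI), nine serum adipokine / inflammatory-factor concentrations
(HMW and LMW adiponectin, adipsin, chemerin, leptin, visfatin, CRP, IL-8,
MCP-1), and all 36 pairwise concentration ratios.  This note documents the
models, the synthetic-cohort generator that stands in for the
access-restricted clinical data, the numerical choices, and what the tests
do and do not establish.

## The predictor: first-order Takagi–Sugeno system with FCM rule induction

The regressor is a fuzzy inference system of R rules.  Rule r is

    IF  z₁ is N(c_{r1}, s_{r1})  AND … AND  z_d is N(c_{rd}, s_{rd})
    THEN  ŷ_r = aᵣ·z + bᵣ

where z is the z-scored input vector (scaling statistics fitted on the
training split only; the target stays in mm³).  The firing strength of a
rule is the product of its Gaussian memberships, and the prediction is the
firing-strength-weighted average of the rule outputs.  Firing strengths are
computed in log space; when an input lies far from every rule center the
normalized weights collapse onto the nearest rule, which serves as the
underflow fallback.

Rules are induced by fuzzy c-means (Bezdek alternating optimization,
fuzziness m = 2, tolerance 1e-8 on the objective): by default FCM runs on
the joint (inputs, standardized target) space so that clusters respect the
response surface, and premises are then projected onto the inputs.
Premise centers are the cluster centers; widths are membership-weighted
within-cluster standard deviations, floored at 1e-4 in scaled units.
Degenerate clusters (vanishing total membership) are dropped with a
warning.

Training is hybrid.  Each epoch: (1) all consequent coefficients are
re-solved exactly by global linear least squares with premises frozen
(minimum-norm solution when the system is singular), so the training RMSE
cannot increase across this pass; (2) premise centers and widths take one
gradient-descent step on the squared error (learning rate 0.01, halved and
reverted whenever a step increases the error; widths floored).  Defaults:
50 epochs, stopping when an epoch improves RMSE by less than 1e-10.  With
one rule the model is exactly ordinary least squares; this is asserted in
the tests to 1e-8.

The rule count is either fixed or chosen from {2, 3, 4, 5} by held-out
error on an internal 70/30 split of the training data — the same 70/30
proportion the study design uses everywhere.

## Variable selection: memetic PSO over subsets, AIC over sizes

With 48 candidate features there are 2⁴⁸ − 1 ≈ 2.81·10¹⁴ non-empty subsets
(≈ 8.44·10¹⁴ across the three BMI strata), so the subset lattice is
searched, not enumerated.  Each particle carries 48 continuous scores and
decodes to the subset of the M highest scores (ties resolve to the
canonical feature order), which pins the subset size exactly — one best
model per size, as the study design requires.

The wrapper fitness of a subset is 0.7·RMSE_train + 0.3·RMSE_test of a
surrogate regressor, averaged over k = 4 cross-validation folds.  The
default surrogate is ridge regression on standardized features
(λ = 1e-3); a single-hidden-layer feed-forward network (8 tanh units,
weight decay 1e-3, full-batch Adam) is available behind the same interface
(`SwarmConfig.surrogate="ann"`).  For the ridge surrogate the fitness is
evaluated through precomputed per-fold centered Gram matrices, making a
subset evaluation O(M³) independent of the sample count; the fast path is
asserted equivalent to the direct fit at 1e-9 relative in the tests.

The swarm uses the standard global-best update
w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x) with swarm 30, 100 iterations,
inertia decaying linearly 0.9 → 0.4, c1 = c2 = 2.0, and velocity clamped to
±4 (positions are initialized uniformly on the clamp range so the two
scales agree).  Two reliability devices are added, both switchable: a
particle whose personal best stalls for 5 evaluations is reinitialized at
random, and after the swarm finishes the incumbent subset is refined by
greedy single-feature swaps to a local optimum.  Plain PSO with the
defaults above located the known planted optimum over 48 features in only
~20-50% of seeded runs; with restarts and the swap refinement, recovery is
essentially always achieved, and on 12-candidate problems the search
matches exhaustive enumeration (which it can never beat — its fitness
values come from the same evaluator).

Stability is assessed by Monte-Carlo repetition: the search is rerun over
`mc_repeats` (default 10) independent fold resplits with seeds derived
from the master seed; each feature's selection frequency is the fraction of
repeats that chose it, and the reported subset is the modal one (ties go to
the best mean fitness).  The first repeat reuses the master seed, so one
repeat degenerates exactly to a single search.

Subset size is chosen by the Akaike Information Criterion,
AIC = n·ln(SSE/n) + 2p with p = M + 1 (variables plus intercept).  The SSE
deserves care: the per-size subsets are themselves optimized by search, so
in-sample SSE — and even SSE cross-validated within the same rows the
search saw — rewards whichever spurious feature happened to correlate with
the realized noise, a best-of-many bias that the 2-point parameter penalty
cannot offset.  The package therefore runs selection on the 70% training
split only and feeds AIC the winning subset's OLS error on the untouched
30% holdout (n = holdout size).  Under this scheme the size scan recovers
the true planted size in ≥ 80% of seeded replicates.

## Evaluation statistics

For observed o and predicted p (both mm³, o > 0): R is the Pearson
correlation; SI = RMSE / mean(o); MAPE = 100·mean(|o − p|/o);
RMSRE = sqrt(mean(((o − p)/o)²)); and the fraction of samples with relative
error below 10% and 15% is reported.  SI is normalized by the mean (not the
range) of the observed values; both conventions exist, and the choice is
isolated in the `metrics` module.  Relative errors always use observed
denominators, and a zero observation is a hard error.

Uncertainty: with e = p − o, SDFE is the sample standard deviation of e
(ddof = 1) and the 95% uncertainty band is centered at the bias-corrected
prediction p − mean(e) with halfwidth 1.96·SDFE; both the halfwidth and
the total width (WUB) are reported, along with the observed coverage.  On
Gaussian residuals at n = 10,000 the coverage calibrates to 0.94–0.96.

Taylor-diagram coordinates (σ_pred/σ_obs, R, centered RMS difference) use
population standard deviations so the law-of-cosines identity
cRMS² = σ_o² + σ_p² − 2σ_oσ_p·R holds to machine precision.  The module
emits coordinates, not figures.

## Synthetic cohorts

The generator emulates the structure of an osteoarthritis imaging cohort
without reproducing any real marginals:

* n = 678 subjects by default; gender Bernoulli with female fraction
  290/678 (coded 0 = female, 1 = male); age uniform on [45, 79] years.
* BMI a two-component normal mixture — N(26.5, 2.5²) and N(34, 3²) with
  equal weight — so the obese (BMI ≥ 30 kg/m², inclusive) and non-obese
  strata are populated roughly equally.
* Biomarkers log-normal with plausible serum medians and log-sd 0.472
  (coefficient of variation ≈ 0.5, the right-skew typical of serum
  assays).  The two adiponectin isoforms share a latent Gaussian factor
  giving log-scale correlation 0.58; other biomarkers are independent.
* IPFP volume = 20000 + 7000·male + 250·BMI − 50·age + 1500·(adipsin/CRP)
  + ε, ε ~ N(0, 1500²) mm³.  The male offset makes volume larger in men by
  construction; the signal routes through adipsin/CRP so that ratio is the
  recoverable truth in selection tests.  An optional gender×ratio
  interaction term (off by default) creates a cohort where gender-separated
  models provably beat a pooled capacity-limited model.
* The external validation cohort defaults to n = 80, female fraction
  57/80, and a BMI profile shifted +2 kg/m² (a higher-severity population),
  sharing the planted generator so transfer is well defined; its subject
  identifiers never overlap the training cohort and the validation entry
  point rejects any overlap at run time.

Effect sizes were chosen so each planted variable is individually
detectable at n = 1000 (t-statistics roughly 10–50) while noise keeps test
MAPE in the few-percent range.  What passing tests show: the machinery
recovers a known sparse linear-in-features signal, calibrated uncertainty,
and deterministic pipelines.  What they do not show: performance on real
cohorts, where effects are weaker, biomarkers are mutually correlated,
missingness exists, and the true response is not linear in any fixed
feature set.

## Study orchestration

`stratify` splits a cohort into Total / High-BMI (≥ 30, inclusive) /
Low-BMI; gender strata use the 0/1 codes.  Each stratum's published
5-variable model ("model #5": age, gender, BMI, adipsin/CRP, plus
adipsin/chemerin for Total, chemerin/adiponectin-HMW for High-BMI, IL-8
for Low-BMI) is built in as the default for the ablation, gender and
inverse-ratio studies, and can be overridden by a fresh selection result.
Ratio names resolve in either orientation: the canonical stored column is
numerator-before-denominator in the fixed biomarker order, and the
resolver returns the reciprocal when a name is flipped.

The ablation grid enumerates all sub-subsets of model #5 with 2–5
variables: 1 + 5 + 10 + 10 = 26 models, labeled M1–M26 on a shared
train/test split.  The 25-row published-style view keeps only nine of the
ten 3-variable models; which one the original table omitted is not
recoverable, so the last enumerated 3-variable subset is flagged rather
than dropped.

The gender comparison fits one pooled and two gender-specific models on
identical row-level splits (training-set identifiers are hashed and logged)
and reports 100·(MAPE_pooled − MAPE_separate)/MAPE_pooled per gender.  The
inverse-ratio study trains twin models on the ratio columns and their
reciprocals with identical seeds and splits.  External validation is pure
evaluation — no refitting — and exports the observed-vs-predicted scatter.
`export_pseudocode` writes the fitted rule base twice: a JSON document that
round-trips predictions bit-for-bit (Python floats serialize via their
shortest exact representation), and a human-readable IF/THEN listing with
the scaler stated, sufficient for independent re-evaluation.

One master seed fixes the cohort draw, splits, FCM initialization, swarm
trajectories and fold resplits, so every reported number is reproducible
byte-for-byte.

## Problem sizes used in the shipped analyses

The numbered drivers under `analysis/` and the acceptance script run at
n = 678–1000 with swarm 20–30 and 25–100 iterations, 5–10 Monte-Carlo
repeats, and 20 seeded replicates for rate estimates.  These sizes were
chosen to make every stage's statistical behavior visible (selection
frequencies, AIC argmin rates, coverage) at desk scale; all of them are
config fields, and nothing in the package depends on these particular
values.

## Known limitations

* The surrogate inside the swarm is (by default) linear; a subset whose
  value is purely non-additive would be mis-ranked.  The ANN surrogate
  mitigates this at ~100× the cost.
* FCM is run once per fit with a seeded random membership initialization,
  not multi-started; pathological initializations are possible in
  principle.
* The published statistics of the original cohort (per-biomarker
  distributions, exact hyperparameters of the neuro-fuzzy fit) are not
  public; all defaults here are declared choices, not reproductions.
* Gender is modeled as the binary code the source data uses; nothing in
  the machinery depends on that encoding beyond the 0/1 convention.
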