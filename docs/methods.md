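# Methods

This note documents the statistical model behind `trajsurv`, the design
choices that were genuinely open, the synthetic-cohort generator and its
limits, and the numerical conventions used throughout.

## 1. Survival model and training loss

All three risk models are proportional-hazards models: each maps a
patient's covariates to a scalar log-risk η, and the conditional survival
function is S(t|x) = exp(−H₀(t)·e^η). Training maximises the Cox partial
likelihood, which depends only on the ordering of risk scores within risk
sets and not on H₀. Tied event times share the full risk set (Breslow
convention); the Cox fitter optionally uses the Efron correction, the
networks always use Breslow so that the three models optimise the same
loss. The loss is averaged over events, which keeps minibatch gradients on
a comparable scale across batches.

The baseline cumulative hazard is estimated after training by the Breslow
step-function estimator on the full training data using the final model's
scores. With all scores zero it reduces to the Nelson–Aalen estimator.

### The two networks

The feed-forward model is deliberately shallow: one hidden fully connected
layer (default width 32) with ReLU, batch normalization and dropout
(default 0.3), then a linear output unit. It consumes the *expanded* data
view, where a time-varying covariate appears as two independent columns.

The recurrent model has two branches. A recurrent cell (default: Elman
cell with tanh, hidden width 16; a GRU is available by config) reads the
two-step sequence of time-varying covariates and emits its final hidden
state; the invariant covariates pass through the same fully connected
stack as above; the concatenation feeds a linear output layer. Layer
widths are package defaults, not values taken from any reference: with
only two time steps and a handful of sequence channels, widths beyond a
few dozen units only add overfitting capacity.

Both networks train with Adam at learning rate 0.05 and batch size 64,
risk sets computed within each minibatch; batches that contain no event
carry no partial-likelihood information and are skipped. Training stops
when the full-training-set loss (evaluated with batch-norm statistics
frozen) has not improved by at least 1e−6 for 20 consecutive epochs, up to
a 1000-epoch cap; the parameters of the best epoch are kept. Early
termination monitors the *training* loss, not a validation split — the
protocol this package reproduces does the same — so it limits wasted
epochs but not overfitting; at registry scale (a few hundred patients,
<100 events) both networks will overfit, and cross-validated or temporal
validation estimates are the only honest performance measures. The
engine is a small hand-written numpy forward/backward implementation
(dense, batch-norm, dropout, Elman/GRU cells, Adam); all randomness
(initialisation, shuffling, dropout) flows from one seeded generator, so
whole training runs are bit-reproducible.

The learning rate 0.05 is aggressive for deep nets; it is kept as the
protocol default but is a config field, and the test-suite experiments
use reduced epoch caps (networks on these cohorts converge long before
1000 epochs).

### Penalized Cox

The Cox fitter maximises the summed log partial likelihood minus
(λ/2)‖β‖² by Newton's method with backtracking line search, to a gradient
norm below 1e−6. The default λ = 0.05 acts as the stabiliser used in the
reproduced protocol ("a penalty [of] 0.05 to the size of the
coefficients" is read as an L2 coefficient penalty). Wald statistics come
from the inverse penalized Hessian; the univariate screen uses λ = 0.

## 2. Predictor screening

Order of operations: missingness filter → simple imputation → univariate
Cox screen + LASSO Cox screen → union → collinearity thinning → Z-score
standardization.

- **Missingness**: a covariate is dropped when missing in strictly more
  than 20% of patients; for time-varying covariates each slot is assessed
  and either slot over the threshold drops the whole covariate.
- **Imputation**: unconditional mean (continuous) or mode (binary, ties
  to 0). Multiple imputation is intentionally out of scope at this sample
  size. Fills learned on development data are reused verbatim downstream.
- **Screens** run on expanded columns (the data view shared by the static
  models). The union of the univariate (Wald p < 0.05) and LASSO
  selections is used; intersection is available by flag. The LASSO path is
  solved by the elastic-net Cox solver of scikit-survival with l1 ratio 1,
  the penalty chosen by 10-fold cross-validated partial likelihood on
  internally standardized columns.
- **Collinearity**: among continuous columns, while any |Pearson r| ≥
  0.60 remains, the member of the worst pair with the larger univariate
  p-value is dropped (ties lexicographic).
- **Candidates** are reported at covariate-unit granularity: a
  time-varying covariate is a candidate if at least one of its slots
  survived, so the recurrent model can consume it whole; slot-level
  pruning for the static models is left to back-elimination, which
  operates at slot granularity for them.
- **Standardization**: continuous covariates are Z-scored with
  development-set parameters; the two slots of a time-varying covariate
  share one pooled (mean, sd) so the admission→discharge delta is not
  distorted. Binary covariates stay 0/1.

## 3. Study protocol

Folds are event-stratified (events and censored patients dealt round-robin
after separate shuffles), since with ~15% mortality plain random 10-folds
risk event-free test folds. Back-elimination greedily removes, each round,
the predictor whose removal gives the best mean cross-validated test
C-index, re-evaluating all remaining predictors every round with one fixed
fold split per study. A removal is accepted if it costs no more than a
parsimony tolerance (default 1e−3 C-index units, far below one
cross-validation standard error at these sample sizes): removals cheaper
than that are indistinguishable from performance-neutral, and preferring
the smaller model is the point of the procedure. Setting the tolerance to
zero restores the strict only-if-improving rule.

Validation data never enters screening, imputation, standardization,
elimination or training. This is enforced structurally (the validation
cohort is only ever an argument to evaluation calls) and verified by a
SHA-256 checksum over all fitted state — imputation fills, Z-score
parameters, model weights including batch-norm running statistics, and the
baseline hazard — taken before and after validation scoring.

## 4. Evaluation

- **Harrell's C-index**: comparable pairs are (i, j) with t_i < t_j and
  δ_i = 1; tied scores count ½; tied event times are not comparable.
- **Time-dependent AUC** (cumulative/dynamic) and **Brier score** use
  inverse-probability-of-censoring weights from the reverse Kaplan–Meier
  estimate of the censoring distribution on the evaluation set, with left
  limits G(t⁻) for observed events (Graf/Uno conventions). Horizons with
  no case, no control, or zero censoring survival are reported as NaN
  ("undefined"), never silently dropped; the low-level functions raise
  when weights are undefined.
- **Calibration**: patients are split into deciles of predicted event
  probability 1−S(h|x) at h = 12 and 24 months; each decile's observed
  event probability is 1 minus the within-decile Kaplan–Meier at h. The
  test statistic is Σ (obs−pred)²/Var_Greenwood(KM), i.e. the survival
  (GND-style) adaptation of the Hosmer–Lemeshow test: the naive binomial
  variance p(1−p)/n is anti-conservative under censoring (measured null
  rejection 8% at nominal 5%). Against its measured null distribution the
  statistic is referred to χ² with (valid groups − 1) degrees of freedom
  (measured null rejection 5.5%). Deciles with nobody at risk at the
  horizon or zero variance are flagged and excluded.
- **Risk stratification**: the floor(0.20·n) patients with the highest
  risk scores form the high-risk group (under proportional hazards this
  is identical to ranking by predicted survival at any horizon); score
  ties break by patient id for determinism. The groups are compared by
  event fractions, Kaplan–Meier curves and the two-group log-rank test.
- Default horizon grids run every 3 months to 48 months on development
  data and 24 months on validation data, avoiding horizons where nearly
  all patients are censored.

## 5. Synthetic cohorts: what they emulate and what they do not

The generator draws invariant covariates (Gaussian or Bernoulli),
admission values Z_A ~ N(μ, σ²), and discharge values Z_D = Z_A + Δ with
Δ ~ N(0, δ²) independent of Z_A. The true log-risk is linear:

    η = Σ β_inv (X − μ_X) + Σ β_D (Z_D − μ_D) + Σ β_Δ Δ,

(covariates centred so the baseline scale keeps its interpretation), and
event times are Weibull proportional hazards,
T = scale · e^{−η/shape} · (−log U)^{1/shape}, censored by the minimum of
an administrative cut-off — optionally staggered-entry: follow-up runs
from a random admission date to one fixed study end — and an exponential
random-censoring time.

The default registry preset has 562 development + 168 validation patients
and 19 candidate covariates named after typical heart-failure predictors
(age, NYHA class, LVEF, log NT-proBNP, eGFR, SBP, DBP, HR, an ADL score,
…), effects of plausible magnitude (|β| ≈ 0.1–0.4 per SD), Weibull shape
1.2, and scale calibrated once so the development cohort shows ~14–15%
mortality over a ~28 ± 12-month staggered-entry follow-up. The validation
preset admits patients later, caps follow-up at 24 months and uses a
shorter baseline scale (a somewhat sicker population, ~16% two-year
mortality) — the calendar drift a temporal split is meant to probe. The
ADL burden is modelled as a continuous score rather than a binary flag so
that it can carry a trajectory term.

Because Δ is explicit, the oracle score is in closed form, and the
information content of restricted views is analysable exactly: a model
seeing only discharge snapshots loses the part of β_Δ Δ not recoverable
from Z_D (the best discharge-only score shrinks β_Δ by δ²/(σ²+δ²)), which
the test suite verifies as a concordance gap ≥ 0.02 at n = 5000.

**Limits.** η is *linear* in (X, Z_A, Z_D). Consequently the expanded
two-column view is a sufficient representation, and a correctly specified
Cox model on expanded columns attains the oracle ceiling at moderate n.
On such data the recurrent model cannot systematically out-discriminate
the static comparators — any advantage of sequence modelling must come
from structure (non-linearity, interactions, measurement noise) that this
generator deliberately does not contain. Passing tests on these cohorts
therefore demonstrate correctness of the machinery and the information
value of trajectories per se, not a generic superiority of recurrent
models; on real cohorts the ordering is an empirical question. Other
non-goals: missingness is MCAR only, there are no competing risks, no
covariate correlations beyond the A/D coupling, and exactly two time
steps.

## 6. Numerical conventions and degenerate inputs

- Time unit is months everywhere; follow-up is measured from discharge.
- Missing values live in an explicit boolean mask; CSV round-trips write
  them as empty cells and reproduce the mask bit-exactly.
- Log-sum-exp reductions are max-shifted; the partial likelihood and its
  gradient match brute-force enumeration to 1e−10 and finite differences
  to 1e−5 relative error.
- Zero events: partial likelihood, log-rank and baseline estimation raise;
  cross-validation skips and flags event-free test folds; fold assignment
  warns and degrades to plain random folds when events < folds.
- Constant covariates make standardization raise (by name); fully missing
  covariates make imputation raise (they should have been filtered).
- Determinism: every stochastic component (generator, fold assignment,
  network initialisation, shuffling, dropout) derives from explicit seeds;
  repeated runs are bit-identical, which the suite asserts for whole
  training trajectories.

## 7. Problem sizes used by the test suite

Experiment sizes are chosen so statistical assertions have adequate power
while the suite stays quick: oracle-equivalence checks use ≥100 random
instances of n ≤ 50; gradient checks n ≤ 20; parameter recovery 100
replicates at n = 2000; the type-I-error simulation 1000 replicates at
n = 150; model-comparison experiments n = 1500/400 over 5 seeds with a
200-epoch cap; back-elimination recovery 10 seeds at n = 1000; calibration
20 replicates at n = 2000.
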