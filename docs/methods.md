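# Methods

## The model

Each participant's momentary symptom dynamics are described by a stationary
lag-1 graphical vector autoregression (GVAR) over p = 6 symptom composites
(anhedonia, depressed mood, appetite change, restlessness, irritability,
lethargy):

    y_t = mu + B (y_{t-1} - mu) + eps_t,    eps_t ~ N(0, K^{-1})

* `mu` — person-specific means. The networks encode deviations from a
  person's own average, so `mu` is always free per person.
* `B` — the **temporal network**: `B[i, j]` is the partial regression effect
  of variable j at the previous beep (3 h earlier) on variable i now.
  Stationarity requires the spectral radius of `B` below 1.
* `K` — the innovation precision. Standardized as
  `omega_ij = -k_ij / sqrt(k_ii k_jj)` it gives the **contemporaneous
  network** of residual partial correlations, associations inside one 3 h
  window after lagged effects are removed.

The sampling frame is a fixed grid of 5 beeps/day over 28 days (140 slots);
a beep not answered within its window is missing.

## Estimation

The unregularized fit is full-information maximum likelihood: the Gaussian
likelihood of all observed entries, with missing entries marginalized by a
Kalman filter on the identity-observation state space (no measurement
noise). The chain is treated as one contiguous lag-1 process over the
140-slot grid; overnight gaps get no special handling, matching the fixed
3 h design.

The fitted objective is the *conditional* likelihood given the first grid
slot (contributions from t >= 2; the first slot enters the filter through the
stationary prior but is not scored). With complete data this is the classical
conditional ML of a VAR(1), whose closed form — lag-pair least squares plus
the residual covariance MLE — the fitter reproduces to numerical precision.
`loglik_gvar` also exposes the exact likelihood (first point scored under the
stationary law), which is what the brute-force joint-Gaussian test oracle
checks.

Optimization is EM: the E-step is a Rauch–Tung–Striebel smoother yielding
smoothed first/second moments and lag-one cross-covariances; the M-step is
the closed-form regression update of (intercept, B, Sigma). This choice has
three properties worth the deviation from a generic quasi-Newton search:
the objective is monotone non-decreasing by construction, Sigma remains
symmetric positive definite without reparameterization, and the complete-data
fixed point is exactly the conditional-ML closed form. Convergence is
declared at a relative log-likelihood change below 1e-6 (maximum 500
iterations); initialization is lag-pair least squares on mean-imputed data,
shrunk below spectral radius 0.95 if needed. Free parameters:
p + p^2 + p(p+1)/2 = 63 at p = 6.

Fits refuse fewer than 30 completed assessments and warn below 75, the
floor recommended for recovering 6-node person-specific networks.

### Regularized fit

For sparse display networks, `fit_gvar_lasso` alternates (i) an L1-penalized
regression of each variable on the lagged vector (objective
`0.5 ||r - Xb||^2 + lambda_B ||b||_1`) and (ii) a graphical-lasso update of K
on the residual covariance, with missing entries replaced by their smoothed
expectations at the current parameters between alternations. Each penalty
pair on a log-spaced grid (default 20 points per axis, from the
empty-network penalty down to 1% of it) is scored by
`BIC = -2 loglik + log(n_obs) * df`, with the observed-beep count as
effective sample size and df counting means, nonzero temporal edges,
innovation variances and nonzero upper-triangle precision entries; the BIC
minimizer is selected. Failed grid points are skipped with a warning; inference
always uses the unregularized fit.

## Preprocessing

* **IDS-SR scoring.** 30 items scored 0–3; respondents answer either the
  appetite-decrease or -increase item (11/12) and either weight item (13/14),
  so 28 items are scored and the total spans 0–84 (if both pair members are
  answered the larger is scored). Severity bands: 0–13 none, 14–21 mild,
  22–30 moderate, 31–38 severe, 39+ very severe.
* **Severity groups.** One group per total attained by at least two
  participants; unique-total participants are reported as excluded.
* **Composites.** Reverse-scored items map x -> 100 - x; each symptom is the
  mean of its available indicators and missing only when all indicators are
  missing (with whole-beep missingness the partial case is rare).
* **Detrending.** Every variable is regressed on the centered-and-scaled
  beep index and its square and cube (observed points only; the global
  1–140 index is the time axis since the grid is equally spaced by design)
  and replaced by the residuals. All variables are detrended
  unconditionally; the trend coefficients are retained as diagnostics.
  Requires 8+ observed points per variable.
* **Stationarity screen.** Augmented Dickey–Fuller per variable on the
  concatenated observed values (constant-only regression, AIC lag
  selection), alpha = 0.05, any-fail rule; constant variables fail with a
  "zero variance" reason. The screen flags participants for exclusion rather
  than dropping them. The specific diagnostic is this package's choice — the
  stationarity assumption itself is standard, the test used to police it is
  not prescribed.

## The invariance test

For a severity-matched group of m members, two models are compared:

* **free/heterogeneous** — independent per-member GVARs; pooled loglik is the
  sum; 63 m parameters;
* **constrained/homogeneous** — one B and one K shared by all members
  (all temporal entries including the autoregressive diagonal, and all of K
  including the innovation variances — the constraint is joint, with no
  carve-out), means free per member; p^2 + p(p+1)/2 + p m = 57 + 6 m
  parameters. The pooled EM M-step solves the shared regression from
  within-member-centered sufficient statistics; initialization averages the
  free fits.

The group is flagged heterogeneous iff
`AIC_free = 2 k_free - 2 ll_free < AIC_constrained`; an exact tie resolves to
homogeneous, keeping the test conservative. Nesting guarantees
`ll_constrained <= ll_free`, asserted in tests after every paired fit.

## Aggregation

* **Proportion.** Members of flagged groups over all matched participants,
  reported to 3 decimals.
* **Bootstrap CI.** Severity groups (not individuals) are resampled with
  replacement to the original group count; flags are held fixed per group
  (groups are independent, so re-running the test inside each replicate
  would change nothing); 10 000 replicates; percentile 2.5/97.5 interval.
* **Null simulation.** Per replicate: a null study (every group's members
  drawn from one true model), detrending, the invariance test per group, and
  the flagged-member proportion. Groups that fail to fit are excluded from
  numerator and denominator and counted — a numerical failure is not
  evidence of heterogeneity. Replicate seeds derive from the master seed via
  spawn keys, so extending the replicate count leaves earlier replicates
  unchanged. The detrending step is included (matching the real pipeline);
  the stationarity screen is not used to exclude simulated participants,
  whose generating processes are stationary by construction.

## What the generator emulates — and what it does not

Defaults mirror the study conditions: 140-slot grid, 18% whole-beep MCAR
dropout (reproducing the observed mean completion of ~115/140), 23 severity
groups with 2–6 members each (~73 participants), and severity totals drawn
from 15–51, the range observed in currently depressed outpatients. Group
ground-truth networks are random sparse stable GVARs — temporal density 0.3
with |edge| <= 0.4, precision off-diagonal density 0.3 via diagonal
dominance — a stand-in chosen once, since the study's real estimated
networks are not public. Alternative (power) studies add +/- effect_size to
a random subset of each member's temporal cells, rescaled back to stability
when needed.

Simulation runs on the latent continuous scale by default; an optional VAS
mode clips to [0, 100]. The Gaussian likelihood theory — and therefore every
oracle equivalence in the tests — is exact only on the latent scale.
Real EMA data differ in ways the generator does not model: missingness tied
to symptom state (MNAR), circadian and weekend structure, item-level skips,
floor effects of the bounded scale, and non-Gaussian innovations. Passing
tests certify the estimator and test under the model's own assumptions, not
robustness to those violations.

## Numerical choices and edge cases

* Burn-in of 100 steps before the retained series; stable B makes this ample.
* The Kalman update uses Cholesky solves throughout; predicted covariances
  are at least Sigma, so innovations stay well-conditioned even right after
  a fully observed beep collapses the state covariance to zero.
* Residual-covariance M-steps apply a relative eigenvalue floor (1e-10) as a
  guard; constant or near-unobserved variables raise a singular-information
  error instead of producing a degenerate fit.
* A non-stationary M-step iterate is handled by falling back to a diffuse
  initial covariance for the next E-step; a non-stationary *final* estimate
  warns rather than errors (the likelihood is still well-defined
  conditionally).
* Determinism: identical input yields bit-identical estimates; all
  simulation randomness flows from explicit integer seeds or generators.

## Problem sizes used by the shipped checks

The acceptance script runs the null simulation at the full study geometry
(23 groups, ~73 members, 140-beep grid, 18% missingness) with 20 replicates —
enough for a Monte-Carlo standard error near half a percentage point on the
false-detection rate. Parameter-recovery checks use 100 simulated persons at
the study scale; operating-characteristic checks use 50 replicates per
condition with two-member groups; consistency checks use T = 5000.

## Known limitations

* Whole-beep MCAR is the only missingness mechanism; no MAR/MNAR.
* Lag 1 only; no regime switching, no multilevel pooling across persons —
  inference is strictly idiographic.
* The AIC comparison localizes nothing: a heterogeneous flag says the group
  differs somewhere, not which edges differ.
* The constrained model shares the full (B, K) including innovation
  variances; a variant with free variances would change the test's
  parameter accounting and was not pursued.
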