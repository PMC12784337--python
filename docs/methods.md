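# Methods

## Model

GMR3 (generalized mixed reduced-rank regression) regresses R response
variables of mixed type — numeric (Gaussian), binary (Bernoulli-logit) and
ordinal (cumulative logit) — on P predictors of mixed type (numeric,
binary, nominal, ordinal) through a shared low-rank structure.  Each
response is driven by a canonical parameter

    theta_ir = m_r + phi_i' B v_r,

where phi_i collects the *transformed* predictor values for participant i,
B (P x S) are regression weights, v_r (length S) are the loadings of
response r, and the rank S < min(P, R) is chosen by the user or by model
selection.  The implied coefficient matrix is A = B V' (P x R).  For
identification, V'V = I and U'U is diagonal with U = Phi B; ordinal
responses carry no intercept (m_r = 0) but C_r - 1 strictly increasing
thresholds t partition their latent logistic variable into categories.

Numeric predictors enter as z-scores.  Discrete predictors are *optimally
scaled*: each category c of predictor p receives an estimated score
w_pc, with the quantified column G_p w_p constrained to mean 0 and
variance 1, and — for ordinal predictors — w_p monotone in the category
order.  The quantifications are estimated jointly with (m, B, V, t,
sigma^2) by maximum likelihood, so one scaling per predictor is optimal
for all responses simultaneously.

The negative log-likelihood assumes conditional independence of the
responses given the low-rank structure and sums per-element losses:
Gaussian with a single shared residual variance sigma^2 across all
numeric responses, Bernoulli-logit, and cumulative-logit category
probabilities pi_irc = F(t_c - theta) - F(t_{c-1} - theta).

## Algorithm

Estimation uses majorization-minimization.  Every per-element loss is
bounded above by a quadratic with shared curvature
kappa* = max(1/4, 1/sigma^2), turning each outer iteration into weighted
least squares on the working-response matrix Z = Theta - Xi / kappa*,
where Xi holds the per-element first derivatives: (theta - y)/sigma^2
(numeric), -(y - pi) (binary), and 1 - 2 E(p | y, theta, t) (ordinal; the
EM expectation of the latent logistic probability-integral variable,
which equals the interval midpoint (F(t_{y-1}-theta) + F(t_y-theta))/2).

Per outer iteration, on a Z computed once from the current support point:

1. quantifications, cyclically over discrete predictors (closed-form
   diagonal least squares; ordinal scores cone-projected by weighted PAVA
   run in both directions, keeping the better weighted SSE; rescale to
   mean 0 / variance 1);
2. B = (Phi'Phi)^{-1} Phi' Z~ V (the Kronecker-structured normal
   equations collapse because V'V = I);
3. V by orthogonal Procrustes (SVD of B'Phi'Z~);
4. intercepts as column means of Z - Phi B V' (numeric/binary only);
5. sigma^2 from the observed numeric residuals, denominator N*R_N - 1;
6. thresholds per ordinal response by exact ML with theta fixed,
   L-BFGS-B on the (t_1, log-gaps) parameterization, warm-started from
   the current thresholds so the step can only descend.

Iterations stop when the NLL decrease falls below `tol` (default 1e-6
absolute) or at `max_iter` (default 1000).  The NLL trace is checked to
be non-increasing to 1e-8 and the fit raises otherwise — an increase
would indicate a majorization bug.  After convergence the solution is
rotated to principal axes (eigenvectors of U'U, descending) with each V
column's largest-magnitude entry made positive; A = BV' is invariant to
this rotation.

Starting values come from a classical reduced-rank regression with all
variables coded numerically (discrete predictors as standardized integer
codes; responses column-standardized), thresholds from logits of
empirical cumulative proportions, sigma^2 from the OLS residual variance
(floored at 0.1).

### Numerical choices

* "Variance 1" always means the population (divide-by-N) convention,
  for z-scores and quantifications alike; one convention everywhere.
* The Gaussian per-observation constant is log(2 pi sigma^2)/2; this
  affects absolute NLL/AIC/BIC values, never the parameter estimates.
* The sigma^2 refresh uses the N*R_N - 1 denominator, which sits a hair
  above the exact ML minimizer SSE/(N*R_N); the update is therefore
  applied as a safeguarded coordinate step — kept only when it does not
  increase the NLL — so the monotone-descent guarantee is unconditional.
* kappa* is shared by all responses; when sigma^2 < 0.05 a warning is
  emitted (the working responses barely move and the algorithm can
  stall).  Probabilities are floored at 1e-300 before logs; the logistic
  cdf/log-cdf use scipy's saturating forms.
* Quantification sign is fixed (first category negative for
  binary/nominal; ordinal direction chosen by fit) purely for
  reproducibility — the likelihood is invariant.
* Procrustes ties take the first S singular pairs as returned; the
  product q_s p_s' is invariant to joint sign flips, so no extra sign
  convention is needed there.
* Ordinal class prediction uses the half-open convention
  t_{c-1} <= theta < t_c.
* Unseen categories at prediction time are an error: no quantification
  exists for them and silently guessing one would be wrong.

## Parameter count and model selection

    K = (P + R - S) S
        + sum_{discrete p} (C_p - 2)
        + sum_{numeric/binary r} 1
        + sum_{ordinal r} (C_r - 1),

with the null model (S = 0) counting only intercepts and thresholds.
AIC = 2 NLL + 2K, BIC = 2 NLL + log(N) K, and the adjusted McFadden index
Ra2 = 1 - (NLL + K)/NLL_0 with the *total* K in the penalty (pass
K - K_null yourself for the alternative reading; both are consistent with
published roundings).  The null model fits marginal means / proportions /
cumulative-proportion thresholds only.

Cross-validation is L-times repeated V-fold on participants; each
training fit is warm-started from the full-data solution of the same
rank; the prediction error is the held-out per-element NLL summed over
responses and averaged per participant (not additionally divided by R).
The SE per rank is taken over the L*V fold means — the convention the
one-standard-error rule assumes.  Folds are re-drawn (up to 50 tries)
until every training split retains every category of every discrete
variable.

The balanced pairs bootstrap permutes B concatenated copies of the index
vector and slices, so each participant appears exactly B times across
resamples.  Each replicate is refitted (warm-started from the parent
fit) and its (B, V) rotated onto the parent solution by orthogonal
Procrustes before pooling — without this alignment the replicate clouds
would mix arbitrary rotations and the ellipses would be meaningless.
Per variable, the mean and covariance of its S-dimensional cloud define
a confidence ellipse; a predictor or response is flagged significant
when the squared Mahalanobis distance of the origin exceeds the 1-alpha
chi-square quantile with S degrees of freedom.

## Synthetic-data suite

`gen_study1` reproduces seven scenarios with P = R = 8 and true rank 2:
weights B from the QR decomposition of a standard-normal matrix, loadings
V with uniform(-1, 1) entries (not orthonormalized — only the *fitted* V
carries that constraint; comparisons use the product BV', which is
invariant), zero intercepts.  Predictors are i.i.d. standard normal;
numeric responses add unit-variance Gaussian noise, binary responses are
Bernoulli(F(theta)), ordinal responses are multinomial draws from the
cumulative-logit probabilities with thresholds (-1, 0, 1).  Scenario
layouts: `cond1` (numeric X; 4 numeric + 4 binary Y), `gmr3-p1`/`gmr3-p2`
(all-ordinal X, balanced .2/.4/.6/.8 or unbalanced .1/.5/.7/.8 quantile
discretization into 5 levels), `gmr3-r1` (4 binary + 4 ordinal Y),
`gmr3-r2` (4 numeric + 4 ordinal Y), and `gmr3-pr` (both sides 2 binary +
3 ordinal + 3 numeric; ordinal predictors 2 balanced + 1 unbalanced,
binary predictors split at the median or the .8 quantile).

For discretized predictors the *analysis* data carry integer codes 1..C,
while the *generating* linear predictor substitutes the per-category mean
of the latent numeric values, standardized to mean 0 / variance 1.  The
standardization keeps the true BV' on the same unit-variance-predictor
scale as the fitted coefficients, which is what makes the RMSE comparison
between the two meaningful (raw category means carry variances of only
0.49-0.90, most severely for dichotomized predictors).

The second study reuses `gmr3-pr` with true ranks 2/4/7; "weak" variants
replace singular values 3..S_true of BV' with 0.20, leaving a structure
whose trailing dimensions add little signal.  Replication seeds derive
from a master seed by a counter-based scheme, so grids are reproducible
and order-independent.

What the generator does *not* emulate: missing data, survey weights,
unequal response variances, predictor correlation, and any dependence of
responses beyond the shared low-rank structure.  Passing recovery tests
therefore demonstrates correctness of the estimator under its own
assumptions, not robustness to their violation.

## Problem sizes used in the built-in experiments

The packaged experiments run 50 replications for the N=1000 coefficient-
recovery summary and the full 250 replications for the N=100
rank-selection counts; these sizes give Monte-Carlo standard errors well
below the effects being checked.  At N=100 the AIC's rank-2 recovery
rate is sensitive to finite-sample optimism of fully converged ML fits:
rank-4 refits that are tightened by several orders of magnitude change no
likelihood value by more than 1e-4, yet the rank-4 gain distribution
(mean ~16 NLL units for 20 extra parameters) sits right of its
asymptotic chi-square reference, so a handful of replications cross the
AIC margin.  The reported counts are what exact ML under these study
conditions produces.

## Known limitations

* One shared sigma^2 across numeric responses; per-response variances,
  probit links, nominal/count responses, penalized or high-dimensional
  extensions, and missing data are out of scope.
* The orthonormality constraint makes the optimization non-convex in
  principle; multi-start agreement is verified empirically in the tests,
  but global optimality is not asserted.
* Bootstrap ellipses ignore the uncertainty of the preceding rank
  selection.
* Very small residual variances (sigma^2 < 0.05) inflate kappa* and slow
  the algorithm to a crawl; a warning is emitted rather than a rescue.
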