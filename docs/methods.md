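# Methods

## Model

PolyMR estimates the shape of the causal function between a continuous
exposure X and a continuous outcome Y from individual-level genotype data,
using SNPs as instrumental variables. Writing G for the n×m matrix of
standardized dosages and β for the instrument effects on the exposure, the
model is

    X = G·β + ε_x
    Y = Σ_j α_j X^j + Σ_j r_j (X − G·β)^j + τ_y ,

where the α_j (j = 0..k) describe the causal polynomial and the r_j
(j = 1..l) form a polynomial control function in the first-stage residual
ε_x = X − G·β. Because the instruments are independent of confounders, any
confounding (or reverse causation) correlated with the exposure lives in
ε_x; including powers of the estimated residual absorbs it, so the retained
α̂_j estimate the causal polynomial. With k = l = 1 the procedure reduces to
the textbook control-function estimator, whose exposure coefficient equals
the 2SLS slope (asserted in the tests to 1e-8).

Estimation is two-stage OLS: β̂ = (G'G)⁻¹G'x from a joint regression of the
exposure on all instruments (solved by orthogonal decomposition), then OLS
of y on the design [1, x, …, x^k, (x−Gβ̂), …, (x−Gβ̂)^l]. Exposure, outcome
and dosage columns are standardized internally (sample variance, ddof 1);
reported curves are mapped back to the input scales.

## Backward selection

Starting from k = l = 10, exposure coefficients of order ≥ 2 that are not
significant at the Bonferroni-corrected level 0.05/k (denominator fixed at
the initial k, i.e. 0.005) are eliminated iteratively, one per refit, and
residual-correction terms are truncated to the highest surviving exposure
order. The intercept and the linear term are never candidates.

Within an iteration, the *highest-order* non-significant term is removed
rather than the least significant one. Adjacent powers of a (near-)normal
exposure are strongly collinear — corr(z², z⁴) ≈ 0.87 for standard-normal z
— so in the full design the signal of a true low-order term is split across
its higher-order neighbours and individual p values are uninformative.
Removing the least significant term first can therefore eliminate the true
term (e.g. x²) while leaving a ladder of spurious higher even powers that
jointly absorb its signal; top-down removal prunes the unstable high orders
first and gives each surviving term a clean marginal test. In simulation
this raises the correct-order recovery rate for a weak quadratic effect
from roughly one third to ≈ 0.88 and keeps the procedure hierarchical.

Every refit during selection reuses a single thin QR decomposition of the
full 21-column design: the submodel y ~ M[:,S] is solved in the projected
p-dimensional space (Q'y ~ R[:,S] plus the constant out-of-span residual),
which is numerically identical to a fresh orthogonal-decomposition fit and
reduces each refit from O(np²) to O(p³). Agreement of coefficients,
standard errors, p values, covariance and log-likelihood with an
independent OLS implementation is asserted to 1e-8 in the tests.

The PolyMR-L1 variant fixes l = 1 (the standard control-function practice)
with truncation disabled; it is retained as a baseline because quadratic
confounding that the first-order residual cannot absorb appears in it as a
spurious causal quadratic.

## Inference

* **Non-linearity p value** — likelihood-ratio test of the final model
  against the model with exposure powers restricted to {1} but the same
  residual-correction columns, using the Gaussian profile log-likelihood
  ll = −n/2·(log(2π·RSS/n)+1); df = number of retained exposure
  coefficients of order ≥ 2, with p = 1 by convention at df = 0. Without
  backward selection this is a nominal-size test (empirical type-I error
  4.0% at the 5% level over 300 null replicates); after selection the
  combined procedure is conservative by construction, since rejection first
  requires a term to survive the 0.005 screen.
* **Causally explained variance** — r² of the final model minus r² of the
  model retaining only the intercept and residual-correction columns. Note
  that because the first-stage residual is correlated with the exposure,
  the residual-only model explains part of the causal signal too; this
  quantity is therefore smaller than Var(f(X))/Var(Y) (≈ 0.008 rather than
  0.015 under the base simulation settings below).
* **Confidence hull** — coefficients are drawn from N(α̂, Σ̂) (classical
  homoskedastic covariance; an HC0 option exists behind a flag) and each
  drawn polynomial is anchored to 0 at the mean exposure; the hull is the
  pointwise 2.5–97.5 percentile band over draws (default 10,000 for
  reporting, 1,000 in replicate studies). If the covariance is numerically
  indefinite its eigenvalues are clipped at zero.
* **Reverse-causation filter** — instruments whose standardized marginal
  effect on the outcome exceeds (in absolute value) their effect on the
  exposure are removed before fitting; the boundary case is retained.

Standard errors ignore the sampling error of β̂ (the second stage treats
Gβ̂ as fixed); the resulting slight undercoverage is a known property of
the plug-in control-function approach. In replicate studies at the default
settings the predicted hull width matches the empirical spread of estimates
within ~2%, while pointwise coverage of the true curve is ≈ 0.92 rather
than 0.95 — the combined effect of plug-in first-stage error and
post-selection variability in the retained degree.

## Synthetic data

The simulator generates
X = G·β + q_x·U + ε_x and Y = f(X) + q_y·U + q_y2·U² + ε_y with a shared
standard-normal confounder U. MAFs are Beta(1,3) draws resampled into
[0.01, 0.5] (the lower bound prevents monomorphic columns at realistic n;
the upper preserves minor-allele semantics); dosages are Binomial(2, p)
with each column standardized. Effects follow β_i ~ N(0, (p_i(1−p_i))^−0.25)
— the MAF term read as the variance; any constant factor is irrelevant
because β is rescaled so Σβ_i² = h² exactly. Var(ε_x) = 1 − h² − q_x² makes
Var(X) = 1 by construction, and X is re-standardized empirically before f
is applied so the causal function acts on an exactly unit-variance
exposure. Var(ε_y) is set to 1 − Var(signal) (floored at 0.05), so
Var(Y) = 1 by construction as well; this keeps the generative coefficients
on the standardized-outcome scale (the recovery targets 0.1 and 0.05 mean
what they say) and makes the null-effect, strong-confounding correlation
corr(X,Y) = q_x·q_y exact. A fixed `outcome_noise_sd` can be supplied
instead, and both the standardized and raw outcome are retained.

Default scenario parameters (the `base` preset): n = 100,000 samples,
m = 100 causal SNPs, h² = 0.5, moderate confounding q_x = 0.2, q_y = 0.5,
q_y2 = 0, causal function f(X) = 0.1X + 0.05X², instruments filtered at
marginal p < 5×10⁻⁸. Named presets cover null/linear/stronger/weak-
quadratic/cubic/quartic polynomials, exponential, signed-root and three
sigmoid functions, strong/negative/quadratic confounding, and a
high-polygenicity variant (m = 10,000, h² = 0.3).

What the simulator does *not* emulate: linkage disequilibrium between
instruments, pleiotropic instruments (direct SNP→outcome effects), binary
traits, or population structure. Passing tests therefore demonstrate
correctness of the estimator under valid instruments and polynomial (or
smoothly approximable) causal functions, not robustness to instrument
invalidity.

One master seed drives independent sub-streams for genotypes, effects,
confounder and the two noise terms, so a dataset is bit-reproducible and
components can be varied independently. Replicate studies derive the
per-replicate seed from (master seed, replicate index), making aggregation
independent of execution order and trivially parallelizable.

## Replicate evaluation

Curves are evaluated on the standard-normal quantiles of percentiles 1–99
(the exposure is standardized and curves anchored at its mean, so this grid
is common across replicates) and compared with the anchored truth
f(z) − f(0). Reported metrics: per-percentile mean bias and RMSE
(RMSE ≥ |bias| pointwise by construction), scenario-mean RMSE with a
normal-approximation 95% CI over replicates, predicted vs empirical hull
width, pointwise truth coverage, the distribution of the highest retained
exposure order, and mean coefficients by order with eliminated
coefficients counted as zero. Replicates whose instrument screen returns
an empty set are skipped, logged and counted.

## Problem sizes used in the shipped checks

The acceptance script runs 200 replicates at the full default scenario
size (n = 100,000) for both the base and weak-quadratic scenarios, and one
n = 100,000 dataset for the confounding correlation. The test suite uses
smaller replicate counts (and for some properties n = 6,000–20,000 with
m = 20, which keeps per-instrument power comparable) so the whole suite
completes in minutes; tolerances follow the Monte-Carlo or binomial error
of each check at the size used.

## Known limitations

* First-stage estimation error is ignored in second-stage inference (no
  MLE correction), giving slight attenuation and undercoverage.
* Instruments are selected and used in the same sample (winner's curse).
* Non-polynomial causal shapes are recovered only as their polynomial
  approximation over the bulk of the exposure range; extrapolation beyond
  the observed range is meaningless.
* Post-selection inference: the LRT and hull are computed conditional on
  the selected model.
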