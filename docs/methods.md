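# Methods

This note documents the statistical model, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Model

For competing causes `k = 1..K`, the package fits Royston–Parmar flexible
parametric models: a restricted cubic spline of log time on the log
cumulative hazard scale with a complementary log-log link,

    η_k(t | x) = s(ln t; γ_k, m_0) + x β_kᵀ + Σ_l s(ln t; α_l, m_l) x_l .

Two scales are supported.

* **Cause-specific** (`scale="cause_specific"`): `η_k = log H_k^cs(t|x)`.
  Each cause is fitted to the subject-level data with events of other causes
  treated as censored; this is a full parametric likelihood, not a partial
  likelihood, so the baseline is estimated jointly with covariate effects.
  All-cause survival and the CIF follow as
  `S = exp(−Σ_k exp(η_k))`, `F_k(t) = ∫₀ᵗ S(u) h_k^cs(u) du` with
  `h_k^cs = (dη_k/dt)·exp(η_k)` and `dη/dt = s′(ln t)/t`.
* **Subdistribution** (`scale="subdistribution"`): `η_k = log H_k^sd(t|x)`,
  so the CIF is `F_k = 1 − exp(−exp(η_k))` directly and `exp(β)` is a
  subdistribution hazard ratio.  Fitting uses the weighted risk-set
  expansion of Geskus: a subject failing from a competing cause at `T_i`
  remains at risk afterwards with time-dependent weight `G(t−)/G(T_i−)`,
  where `G` is the censoring-survival estimate — Kaplan–Meier by default
  (with deaths preceding censorings at ties and left-continuous
  evaluation), or a flexible parametric model of the censoring distribution
  (`censoring_model="fpm"`, default 3 df, optional covariates).

The likelihood over rows with intervals `(tstart, tstop]`, event flag `d`
and weight `w` is

    ℓ = Σ_i w_i [ d_i (log η′(tstop_i) + η(tstop_i)) − e^{η(tstop_i)}
                  + 1{tstart_i>0} e^{η(tstart_i)} ] .

Both scales, including the expanded weighted data and the stacked
(Lunn–McNeil-style) simultaneous fit of all causes, are special cases of
this one expression.

## Splines and knots

The basis of `ln t` is `z_1 = ln t` and, for `j ≥ 2`,
`z_j = (ln t − m_j)₊³ − φ_j (ln t − m_1)₊³ − (1 − φ_j)(ln t − m_M)₊³`,
`φ_j = (m_M − m_j)/(m_M − m_1)`, linear beyond the boundary knots.  Knots
sit at equally spaced centiles of the uncensored cause-specific log event
times (inclusive linear-interpolation quantiles, fixed for format
stability), boundary knots at the extremes; time-dependent-effect splines
use the same event times at their own df and therefore share boundary knots
with the baseline.  Bases are orthogonalised by default (QR against the
intercept, mean zero, unit scale) for numerical conditioning; the projection
matrix is stored in the model (and its JSON serialisation) and re-applied
verbatim at prediction times, so raw and orthogonalised parameterisations
give identical fits, predictions and log-likelihoods.  Knots are serialised
on the time scale (not log) for readability.

## Estimation

* Start values: weighted Nelson–Aalen cumulative hazard regressed through a
  complementary log-log transform on the design at the event rows; zeros as
  a fallback.
* Optimiser: BFGS with the analytic gradient of the likelihood above (the
  gradient is closed-form; this keeps the simulation studies cheap), with a
  Nelder–Mead restart and re-polish if the score is not within
  `1e-4·(1+|ℓ|)` of zero.  A fit that fails this after restarts raises.
* Hazard positivity: during the search, `log η′` is replaced below a small
  floor (`1e-8`) by its second-order expansion — a smooth penalised
  surrogate — so infeasible iterates do not produce `−∞`; the final model
  must satisfy `η′ > 0` at every event time or it is flagged invalid and
  refuses hazard predictions.
* Covariance: inverse observed information from a central finite-difference
  Hessian of the analytic gradient (step `1e-5·(1+|θ_j|)`), symmetrised.
  For weighted subdistribution fits a cluster-robust sandwich covariance
  (clustered on subject id) is also stored and used by default, because the
  censoring weights are estimated; variance contributions from estimating
  `G` itself are not propagated.
* Likelihood-ratio tests require nested fits on identical data and use a
  chi-squared reference with df equal to the parameter-count difference.

## Numerical integration

All CIF / RMST / life-years-lost integrals use Gauss–Legendre quadrature
with `m = 30` nodes by default (configurable; exact for polynomials of
degree `2m − 1`).  The sub-density `S(u)h_k(u)` of a log-time spline model
behaves like `u^{b−1}` near `u = 0`, which degrades the plain affine-mapped
rule to roughly `O(m⁻²)` convergence.  Prediction integrals over `[0, t]`
therefore apply the change of variable `u = t q²`, `q = (v+1)/2`, before
using the same rule; this restores near-spectral accuracy (the
`S + Σ_k F_k = 1` identity holds to ~`1e-8` at `m = 30`, versus ~`1e-5`
without the substitution).  Life-years lost from cause-specific models uses
a nested rule — the inner CIF integral is evaluated afresh at every outer
node — and RMST is computed as `t* − Σ_k L_k(0, t*)`, so the partition
identity `μ + Σ L_k = t*` holds exactly; the direct `∫S` route is available
(`method="direct"`) and agrees to quadrature accuracy (~`1e-6`).

## Inference on predictions

Standard errors propagate the parameter covariance through each prediction
functional by the delta method with central finite-difference gradients on
the stacked parameter vector of all models involved (block-diagonal
covariance across separately fitted causes; the joint likelihood separates,
so cross-cause covariance is asymptotically zero).  Confidence intervals are
computed on a transformed scale and back-transformed: complementary log-log
for CIFs and survival (keeps intervals in `[0,1]`), log for RMST, RMFT and
life-years lost (positive quantities), identity for differences and log for
ratios.  Default level 95% with normal quantiles.

## Standardisation

Marginal estimates fix the intervention covariates to the requested values
for every individual and average the `N` individual predictions (the
G-formula under time-fixed confounding).  The variance treats the covariate
rows as fixed (conditional-on-sample inference) and applies the delta method
to the averaged functional.  Duplicate covariate rows are collapsed into
multiplicity weights before evaluation — an exact reduction.  Individual
designs at the quadrature nodes are precomputed in chunks (`chunk`
individuals at a time) to trade memory for speed; an external reference
population with per-row weights is accepted in place of the analysis data.

## Synthetic data

`simulate_csh` draws latent cause-specific failure times with cumulative
hazards `H_k(t|x) = λ_k t^{p_k(x)} e^{xβ_k}`, where time-dependent log
hazard ratios linear in `ln t` enter exactly as covariate shifts of the
Weibull shape; observed time is the minimum over causes, exponential
dropout and an administrative window.  `simulate_subdistribution` draws
from the proportional-subdistribution-hazards family
`F_1(t|x) = 1 − (1 − π(1 − e^{−t}))^{exp(xβ)}` by inverting the conditional
CIF, with exponential competing times among the remainder.  The packaged
`colorectal_like` scenario is entirely synthetic: three causes (cancer,
CVD, other), binary deprivation, sex, truncated-normal age 45–90 and a
10-year window, with rates calibrated so the event fractions are roughly
31% / 5% / 20% with 44% alive or censored — the same order as a large
population colorectal registry.  The generators produce proportional (or
log-time-linear time-dependent) effects and independent covariates only;
real registry data exhibit non-PH patterns, correlated covariates, delayed
entry and reporting artefacts that these scenarios do not emulate, so
passing tests demonstrate correctness of the estimators under the stated
families, not robustness to misspecification.

Test and validation problem sizes were chosen as the smallest that leave
Monte-Carlo error well below the tolerances being asserted: n = 50,000 for
closed-form and nonparametric-agreement checks (≈1% accuracy), n = 20,000
across 20 replicates for the Weibull identity, n = 2,000 across 500
replicates for confidence-interval coverage, and n = 500 across 1,000
replicates for the likelihood-ratio type-I error.

## Known limitations

* No delayed entry (left truncation) in input data, and no time-varying
  covariates beyond spline time-dependent effects.
* Only the complementary log-log link (proportional (sub)hazards structure);
  no probit/logit links, no penalised knot selection, no frailty.
* Subdistribution-route variances ignore the estimation of the censoring
  weights (conditional inference, as is conventional for this route).
* The full-likelihood (non-weighted) cumulative-incidence-scale fit is not
  implemented; the weighted-data route is the supported estimator.
* Standardisation assumes time-fixed confounders; no sequential G-formula.
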