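# Methods

## The generating process

Data are generated from a first-order, time-homogeneous vector
autoregression for Z_t = (X_t, Y_t) with two standardized instruments
V = (IVx, IVy) acting on their trait at every occasion:

    Z_1 = C V + e_1
    Z_t = B Z_{t-1} + C V + e_t,   t = 2, …, T

with lag matrix B = [[bX2X1, bXY], [bYX, bY2Y1]] (rows receive, columns
send), instrument loadings C = diag(bX, bY), Cov(V) = [[1, rIV], [rIV, 1]],
and occasion residuals e_t with variances (resid_var_x, resid_var_y) and
cross-sectional correlation rexy, constant over occasions.  Only lagged
paths connect X and Y: in the generating truth the cause precedes the
outcome.  The process is Markovian; when the spectral radius of B is
below 1 it converges to a stationary regime (parameter sets violating
this are rejected at construction).

Defaults: bYX = bXY = 0.2, AR1 = 0.7/0.7, rexy = 0.3, bX = bY = 0.08,
rIV = 0.25, unit residual variances, T = 150 occasions, N = 1000.  These
are the reference simulation conditions: IV effects of 0.08–0.1 on a
unit-residual trait give stationary instrument R² values of roughly 2–8%,
in line with what polygenic scores achieve for behavioral traits, and
AR1 values of 0.5–0.8 bracket commonly observed stability estimates.
Unit residual variances are the unique choice under which those R² values
take their canonical levels (2.09%, 8.03%, 8.26% for the three canonical
parameter sets).

Two equivalent routes to the moments are implemented and cross-checked in
the tests:

* the **full RAM representation** over (IVx, IVy, X_1…X_T, Y_1…Y_T),
  dimension 2(1 + T), with Σ = (I − A)⁻¹ S (I − A)⁻ᵀ;
* the **occasion-wise recursion** on the 2×2 blocks
  q_t = Cov(Z_t, V) and P_t = Cov(Z_t),

      q_{t+1} = B q_t + C Σ_VV
      P_{t+1} = B P_t Bᵀ + B q_t Cᵀ + C q_tᵀ Bᵀ + C Σ_VV Cᵀ + Ψ

  whose fixed points are solved directly (q by a linear solve, P as a
  discrete Lyapunov equation) for the stationary quantities.

Stationarity onset is operationalized as the first occasion at which all
ten unique elements of the cross-sectional covariance of
(IVx, IVy, X_t, Y_t) change by less than 1e-4 in absolute value from the
previous occasion.  Monitoring the IV–trait covariances alongside the
trait block matters because the instrument-relevance R² must also have
stabilized.  The first occasion has no autoregressive input
(Z_1 = C V + e_1); since analyses only use occasions far beyond the onset
index, results are insensitive to this initialization, but the onset
index itself depends on it slightly, so it is fixed as stated.  Stronger
autoregression delays onset; the canonical high-AR bidirectional set
meets the criterion at occasion 65 and the unidirectional set at 50.

Two-wave moments place wave 1 at occasion t1 = 100 (beyond onset for all
canonical sets; enforced) and wave 2 at t1 + ΔT.  They are computed by
the exact finite-t recursion, not the stationary limit, so they agree
with the full RAM matrix to machine precision.

**Exact sampling.** `exact_sample` draws standard normals, centers,
whitens by the empirical Cholesky factor and recolors by the target
factor, so the sample's unbiased (n−1) covariance and means equal the
target moments to machine precision.  Moments computed from data
(`MomentSet.from_dataframe`) therefore default to the n−1 divisor: a
sample → moments → fit round trip reproduces the exact-moment fit
identically.  This is the "empirical" simulation device that makes LRT
statistics equal non-centrality parameters with no stochastic variation.

What the generator deliberately does not emulate: sampling variability
(by design), missing data, ordinal measurement, covariates, time-varying
coefficients, higher-order lags, or more than two traits.  Passing tests
demonstrate the algebra and the estimation machinery under the stated
stationary conditions; they say nothing about robustness to those
real-data features.

## The analysis models

All models are held in RAM form (directed paths A, column-to-row;
symmetric (co)variances S; intercepts m) over observed variables only;
implied moments are Σ = (I − A)⁻¹ S (I − A)⁻ᵀ and μ = (I − A)⁻¹ m.
Parameters are referenced by name, so restricted variants are produced by
re-fixing named parameters to zero.

* **CLPM** (X1, Y1, X2, Y2): two AR(1) paths, two lagged ("distal")
  paths, free wave-specific (co)variances — 10 covariance-structure
  parameters for 10 moments, just-identified.
* **IV regression** (IVx, X, Y): instrument loading, causal path bYX,
  free residual covariance — just-identified; the ML solution for bYX is
  the IV-ratio Cov(IVx, Y)/Cov(IVx, X).
* **Bidirectional IV-CLPM** (IVx, IVy, X1, Y1, X2, Y2): four IV paths
  (each instrument to its trait at each wave), reciprocal proximal pairs
  at each wave, two distal paths, two AR(1) paths, nine (co)variances —
  21 parameters for 21 moments.  The reciprocal pairs make A
  non-triangular; the engine only requires (I − A) to be invertible, and
  the instruments supply the identification (verified numerically: the
  moment Jacobian loses rank when the wave-1 IV paths are cut while the
  reciprocal pair stays free).
* **Unidirectional IV-CLPM** drops IVy and every Y → X causal path
  (14 parameters vs 15 moments, one over-identifying restriction).

IV variances and their covariance are freely estimated rather than fixed
at the generating values; with just-identified models this does not move
the causal estimates but keeps the df bookkeeping uniform.  Intercepts
are always saturated, so mean structure never contributes to
covariance-structure likelihood-ratio tests.

## Fitting and inference

Normal-theory ML minimizes
F(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p + (x̄ − μ(θ))ᵀ Σ(θ)⁻¹ (x̄ − μ(θ)),
reporting −2lnL = n·F plus the saturated constant, so saturated models
attain discrepancy exactly 0 and LRT differences equal n·ΔF (the
multiplier is n, not n − 1; all reported comparisons are differences, so
the additive constant is immaterial).  Because the intercept structure is
saturated, means are concentrated out analytically (m̂ = (I − Â) x̄) and
the optimizer searches only the covariance-structure parameters.

Numerical strategy, in order:

1. **Closed forms first.**  Each just-identified full model has an exact
   solution (the CLPM lagged block is S21 S11⁻¹; the IVR slope is the
   IV-ratio; the bidirectional IV-CLPM solves, per wave, the linear
   moment conditions of each structural row against the instruments and
   the earlier wave).  When available and admissible it is used directly.
2. **Multistart quasi-Newton** (L-BFGS-B on a penalty-guarded objective;
   non-positive-definite Σ draws a large penalty): the builder/warm
   start plus two zero-regression starts.  Restricted nonrecursive
   IV-CLPMs genuinely possess local optima — a single generic start was
   observed to report an NCP of 204 where the true value is 27 — hence
   the multistart, and the interval sweep additionally warm-starts every
   restricted fit from the full model's solution.
3. **Damped Newton polish** with central-difference derivatives, to the
   1e-10 gradient scale needed for exact-moment NCP work, plus jittered
   restarts if a just-identified model has not saturated.

Convergence requires a scaled gradient below 1e-6.  Standard errors are
observed-information (numerical Hessian of −2lnL at the optimum); they
match the analytic large-n regression SE on a single-slope model to ~1%
and scale as 1/√n.  Local identification is checked as the numerical
rank of the Jacobian of the stacked unique moments at the start values
and at random admissible points.

LRTs compare nested fits; with exact moments the statistic is the NCP,
and power is the non-central chi-square upper tail beyond the central
(1 − α) quantile.  Negative NCPs within 1e-8 are floored to zero; larger
negative values raise (they signal non-nesting or failed convergence).
p-values are plain chi-square upper tails, uncorrected — the
6 df → 3 df → 1 df hierarchy is the gatekeeping.  Residual correlations
are reported per wave as C/√(Vx·Vy); at short intervals the IV-CLPM's
wave-1 residual correlation is typically negative even when the
generating residual correlation is +0.3, because the cumulative proximal
effects overshoot the observed cross-sectional covariance.

## The interval sweep and diagnostic

`run_interval_sweep` fits both families at every ΔT = 1…ΔT_max on exact
moments (N = 1000 nominal), recording causal estimates, residual
correlations, and the full NCP hierarchy; a `sampled` mode refits on
exact-moment samples for end-to-end testing.  The per-interval
diagnostic compares NCP(1 df, wave-2 proximal) with NCP(2 df, distal +
wave-2 proximal) per direction: a ratio near 0 says the interval is
short enough for the plain CLPM; near 1, the Granger signal has decayed
and only the proximal machinery retains power.

## Numerical findings worth knowing

* **The CLPM tail does not reach zero when instruments are present.**
  With per-occasion IV effects in the generating process, the lag
  covariance contains a non-decaying component (I − B)⁻¹ C qᵀ that the
  4-variable CLPM cannot marginalize away.  At the reference parameter
  set the CLPM lagged estimate peaks at ≈0.31 (ΔT = 3), is 0.0593 at
  ΔT = 31 and asymptotes at ≈0.042, crossing 0.05 only near ΔT = 38.
  For the same reason the CLPM estimates depend weakly (~2% relative) on
  the generating residual correlation rather than being exactly
  invariant.  Both effects vanish for the IV-free process, whose lagged
  estimand is exactly B^ΔT.  The IV-CLPM's distal estimate, which
  conditions on the instruments, does approach zero at long intervals.
* **Instrument leakage.**  With correlated instruments (rIV ≠ 0), setting
  bX = 0 does not zero the stationary R² of X on IVx: relevance leaks
  through IVy → Y → X (≈0.16% at the defaults).  The R² vanishes exactly
  when rIV = 0.
* **Unidirectional vs bidirectional power.**  On unidirectional-causation
  moments the parsimonious unidirectional model yields slightly smaller
  1 df NCPs than the bidirectional model at moderate intervals (no power
  advantage from parsimony).  At ΔT = 1 the ordering can reverse for the
  distal and wave-2 proximal tests, where the bidirectional model's free
  wave-2 reciprocal path absorbs the restricted signal.

## Problem sizes

Tests and the acceptance script run on 4–6 variable moment structures;
sweeps in the test suite cover a handful of intervals, and the
long-interval acceptance check fits the CLPM at ΔT = 31…50 (closed-form
seeded, a few seconds total).  The full 50-interval both-family sweep
with the complete NCP hierarchy (~16 fits per interval) is the CLI's
job, not the test suite's.
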