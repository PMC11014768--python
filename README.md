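# ivclpm

Cross-lagged panel models with instrumental variables, for studying how
causal estimates depend on the time interval between study waves.

## The problem

The cross-lagged panel model (CLPM) estimates bidirectional Granger-causal
("lagged") effects between two repeatedly measured traits, X and Y.  Those
lagged effects decay as the interval ΔT between the two assessments grows,
so a non-significant lagged effect is ambiguous: either there is no
causation, or the waves are simply too far apart.  Adding one instrumental
variable per trait — in practice often a polygenic score, whose random
segregation at conception supports the exchangeability assumption of
Mendelian randomization — turns each wave into a cross-sectional IV
regression.  The resulting IV-CLPM estimates three kinds of causal effect
per direction:

* **proximal, wave 1** (`bY1X1`, `bX1Y1`) — cumulative causation accrued
  before the first assessment; invariant to ΔT;
* **distal** (`bY2X1`, `bX2Y1`) — the lagged Granger effect across the
  interval; decays toward zero as ΔT grows;
* **proximal, wave 2** (`bY2X2`, `bX2Y2`) — between-wave causation not
  captured by the distal path; approaches the wave-1 proximal effect at
  long intervals under stationarity.

This package implements the full workflow: a RAM-based (Reticular Action
Model) SEM engine with Σ = (I − A)⁻¹ S (I − A)⁻ᵀ, builders for the CLPM,
the IV regression, and the bidirectional/unidirectional IV-CLPM, a
stationary first-order vector-autoregressive data generator with exact
("empirical") moment sampling, maximum-likelihood fitting with
likelihood-ratio tests, and a non-centrality-parameter (NCP) power
workflow over intervals ΔT = 1…50.  With exact population moments as
input, the LRT statistic from fixing parameters to zero equals the NCP of
the non-central chi-square, so power curves carry no Monte-Carlo noise.

## Worked example

```python
from ivclpm import (DataGenParams, stationary_moments, iv_r_squared,
                    two_wave_moments, build_iv_clpm, build_clpm,
                    apply_restrictions, fit_ml, lrt)

params = DataGenParams()  # bYX = bXY = 0.2, AR1 = 0.7, rexy = 0.3
st = stationary_moments(params)
print(f"stationarity index: {st.stat_index}")
print(f"stationary Var(X):  {st.P[0, 0]:.4f}")
print(f"IV relevance R^2:   {100 * iv_r_squared(params):.2f}%")

moments = two_wave_moments(params, dT=5)        # waves at occasions 100 and 105
ivclpm = build_iv_clpm()
fit = fit_ml(ivclpm, moments)
print(f"proximal (wave 1) X->Y: {fit.estimates['bY1X1']:.3f}")
print(f"distal            X->Y: {fit.estimates['bY2X1']:.3f}")
print(f"proximal (wave 2) X->Y: {fit.estimates['bY2X2']:.3f}")

restricted = apply_restrictions(ivclpm, ["bY1X1", "bY2X1", "bY2X2"])
test = lrt(fit, fit_ml(restricted, moments, theta0=fit.estimates))
print(f"3 df test of X->Y causation: NCP = {test.ncp:.2f}, "
      f"power at alpha=0.05: {test.power_at_alpha:.3f}")

clpm = fit_ml(build_clpm(), moments)
print(f"CLPM lagged X->Y: {clpm.estimates['bY2X1']:.3f}")
```

prints

```
stationarity index: 65
stationary Var(X):  4.2973
IV relevance R^2:   7.30%
proximal (wave 1) X->Y: 0.667
distal            X->Y: 0.168
proximal (wave 2) X->Y: 0.358
3 df test of X->Y causation: NCP = 78.47, power at alpha=0.05: 1.000
CLPM lagged X->Y: 0.291
```

Reading the output: the generating series is stationary from occasion 65
on (consecutive cross-sectional covariances change by < 10⁻⁴), the
instrument explains 7.3% of the variance of X at stationarity, and at a
five-unit interval the cumulative (wave-1 proximal) effect 0.667 dwarfs
the lagged effect 0.168 — causation is still detectable here through the
joint 3 df test (NCP 78.5, power ≈ 1) even where the CLPM's lagged
estimate (0.291) is already past its peak and decaying.

The same operations are exposed on the command line:

```
ivclpm simulate --config params.yaml --dt 5 --seed 1 --out sample.csv
ivclpm stationarity --config params.yaml
ivclpm fit --model ivclpm --data sample.csv
ivclpm sweep --config params.yaml --dt-max 50 --out sweep.csv
ivclpm diagnose --sweep-csv sweep.csv
ivclpm power --ncp 7.849 --df 1
```

`diagnose` reports, per interval and direction, the share of the
between-wave causal signal carried by the wave-2 proximal effect — near 0
the plain CLPM is adequate; near 1 the interval is too long for Granger
detection and the IV-CLPM is needed.

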