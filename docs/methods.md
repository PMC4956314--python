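# Methods

## Problem structure

The pipeline estimates how seasonal lake biology responds to the previous
summer's stream discharge when neither series is directly usable: the
discharge record has contiguous gaps (hours to weeks) and the biology is
sampled only a handful of times per season. Stage 1 turns gappy discharge
observations into complete latent curves with uncertainty; stage 2 carries
those curves into a functional linear regression.

All functional objects live on one equidistant daily grid per flow season:
Dec 1 of year *s* through Jan 31 of year *s*+1, Δt = 1 day, M = 61
intervals, 62 nodes, horizon T = 61 days. Daily resolution matches the
gauges' natural daily-average summary; the quadrature below only requires
equidistance. Discharge enters on the offset-log scale DR = log(ζ + Q)
with ζ = 0.01 (in the file's discharge units, configurable), so zero-flow
days map to the finite reference log ζ ≈ −4.61. Units of Q are treated as
opaque and assumed consistent within a file.

## Stage 1: GMRF reconstruction of log-discharge

Per stream and season (independently — melt seasons are separated by eight
months of no flow), daily observations follow

    DR_obs(t_l) = DR(t_l) + ξ(t_l),   ξ ~ N(0, σ_e²) iid
    DR(·) ~ GMRF(mean = δ0 + δ1 T(·), precision = τR)

with T(·) the complete daily air-temperature series. R is the first-order
random-walk (RW1) structure matrix (tridiagonal, zero row sums): the
simplest sparse precision consistent with a smooth single-pulse seasonal
curve. A second-order walk is available behind `gmrf_order`. The RW1 prior
is improper (constants unpenalised); the posterior is proper whenever at
least one day is observed. With no observations the prior mean δ0 + δ1·T
is returned flagged with infinite sd rather than an imputation.

Conditioning is exact and sparse: posterior precision τR + A'A/σ_e² (A
selects observed nodes), solved by sparse LU in `conditional_latent` and
by banded Cholesky inside the sampler. Hyperparameters get vague conjugate
priors — δ0, δ1 ~ N(0, 100²), σ_e² ~ Inv-Gamma(0.01, 0.01), τ ~
Gamma(0.01, 0.01) — and a Gibbs sampler alternates (latent field | rest),
(δ | rest), (σ_e², τ | rest), 2000 kept draws after 1000 burn-in by
default. One banded Cholesky per sweep keeps a season's fit under a
second. A coarse split-chain drift check warns (never fails) on suspect
chains. Because R annihilates constants, δ0 is informed only by its prior;
the level of the curve is carried by the data directly, and δ1 is
identified through the increments. Seasons with fewer than `l_min = 5`
observed days are excluded rather than imputed from the prior.

Downstream, each stream-season contributes its posterior-mean curve (one
curve per pair); propagating posterior draws instead is possible via
`keep_draws` but is not the default.

## Stage 2: scalar-on-function regression

Responses are seasonal scalars: the unweighted mean of all PPR (or CHL)
measurements in October–December at depths ≤ 11 m (the chemocline; the
oxic zone where stream water actually mixes). Depth-weighted integration
was considered and deliberately not applied — sampling is already near
uniform in depth, and the plain mean keeps n_obs interpretable. Each
response year *s* is paired with discharge season *s*−1 (lag one year:
spring biology runs on nutrients delivered before the current melt
starts); the pairing is asserted on every design row.

The functional model Y_i = α + Σ_j ∫ β_j X_ij + ε_i is reduced by an
orthonormal basis. Default: Fourier with K = 5 (constant plus two
sin/cos pairs) — the flow season is one broad pulse, so low frequencies
suffice; cubic B-splines (Gram–Schmidt-orthonormalised under the grid
inner product) are the alternative. Integrals use the left Riemann sum
over nodes 0..M−1; under that inner product the Fourier system is exactly
orthonormal (it is the DFT basis). Scores feed a ridge regression with
unpenalised intercept; λ is chosen per model by closed-form LOOCV over
{0, 1e-4, …, 100}, ties broken toward the larger (more stable) penalty —
relevant because n ≈ 17 is small. The functional covariate is the
log-scale curve DR(·) by default (`covariate_scale: linear` substitutes
exp(DR) − ζ).

One J = 1 model per stream is the headline analysis (a joint J = 3 fit is
available but under-determined at these sample sizes); ensemble
predictions are the arithmetic mean of the per-stream predictions, the
ensemble SE is the root of the mean per-model prediction variance
(smoother-covariance SEs under each model's residual variance, df =
n − tr H), and the reported fit statistic is the arithmetic mean of the
per-model R².

Degenerate inputs: a zero-variance response raises rather than reporting
an undefined R²; n < 3 rows refuse to fit; K > M (super-resolution) is
rejected; with λ = 0 the solve uses a pseudo-inverse so collinear scores
degrade gracefully.

## Synthetic data generator

The generator produces the full input suite in the exact CSV dialects the
ingest layer reads, with truths retained for recovery tests. Defaults
mirror the study scale: 17 response seasons, 3 streams, the 62-node grid.

- **Temperature**: a Gaussian-bump seasonal curve (base −7 °C, amplitude
  9 °C, peak near Dec 31) with per-season anomalies — mean offset sd
  1.5 °C, peak-timing sd 5 days, amplitude jitter 20% — plus 1.5 °C daily
  weather noise. The interannual anomalies are the point of the study
  system (warm vs cold summers) and drive the between-season covariate
  variation the regression needs.
- **Discharge**: latent DR = δ0 + δ1·T + AR(1) deviation (δ0 = −2,
  δ1 = 0.8, ρ = 0.8, σ = 0.5), floored at log ζ so back-transformed flow
  is non-negative; observations add N(0, 0.3²) noise and lose 2 contiguous
  blocks of 3–14 days per season. The AR(1) truth deliberately
  misspecifies the RW1 fitting model, so imputation tests exercise a
  realistic model mismatch rather than a self-fulfilling one.
- **Responses**: Y = α + Σ_j ⟨β_true,j, X_j⟩ + N(0, σ²) through the same
  quadrature the fit uses; β_true is a smooth positive low-frequency pulse
  (γ base [0.02, 0.008, 0.006, 0.002, 0.001], scaled 1/1.5/2 across
  streams): nutrient delivery tracks cumulative flow with extra weight on
  the broad pulse. σ defaults to sd(signal)/3 computed from the realised
  signal (a 3:1 signal-to-noise ratio).
- **Profiles**: 3–4 sampling dates per Oct–Dec window, depths 0.5–18 m at
  0.5-m steps; values scatter (sd 0.3) around the season's Y above 11 m
  and around Y + 3 below it, so the chemocline filter is genuinely
  exercised; values clip at zero.

What the generator does *not* emulate: hydrograph microstructure (diurnal
melt cycles, flood recessions), sediment effects, depth-structured biology
within the oxic zone, non-Gaussian measurement error. Passing tests
therefore certify the statistical machinery under the stated generative
assumptions, not hydrological realism.

## Numerical and reproducibility choices

- Quadrature: left Riemann sum, m = 0..M−1, exactly as the reduction is
  defined; all inner products in the package share it.
- Sparse solves: LU (`splu`) for one-shot conditioning; LAPACK banded
  Cholesky inside the Gibbs loop (bandwidth = RW order).
- Seeding: a single global seed is expanded by CRC-hashing the
  (stage, stream, season) key into independent substreams below 2³¹, so
  adding a stream or season never perturbs other draws; identical
  config + seed reproduces the summary JSON byte-for-byte.
- LOOCV uses the closed-form leverage identity of the linear smoother; a
  leverage of 1 is guarded with a 1e−12 floor.
- Temperature gaps ≤ 3 consecutive interior days are linearly
  interpolated; longer gaps, edge gaps, or > 50% missing abort ingestion.

## Known limitations

- The per-stream (J = 1) models absorb shared-driver signal; their β̂ are
  marginal, not partial, effects. The joint fit exists but is barely
  identified at n ≈ 17.
- Under the deliberate AR(1)-vs-RW1 mismatch the sampler attributes fast
  temperature-coupled fluctuation to observation noise, which attenuates
  δ1 and narrows credible bands inside long gaps (coverage ≈ 0.8 at a
  nominal 0.95 in the held-out-gap experiment reported by
  `scripts/acceptance.py`).
- At a 3:1 signal-to-noise ratio and n = 17 seasons, the coefficient
  *curve* is only partially identified: the quadrature-score design has a
  condition number near 14, so high-frequency components of β are
  estimated poorly even when predictions are good. The recovery-rate
  number the acceptance script reports quantifies exactly this.
- In-sample R² at n ≈ 17 with LOOCV-chosen ridge is optimistic; the
  package reports it because it is the study's fit statistic, not because
  it estimates out-of-sample skill.
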