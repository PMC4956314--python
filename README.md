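# hydrofda

Two-stage statistical pipeline linking glacial melt-stream discharge to
biological activity in a perennially ice-covered Antarctic lake, written
for limnologists and environmental statisticians working with gappy polar
sensor records.

The scientific setting: closed-basin lakes in the McMurdo Dry Valleys are
fed by melt streams that flow only a few weeks per austral summer
(December–January). Lake primary production (PPR, μgC/(L·day)) and
chlorophyll-A (CHL, μg/L) in the following austral spring (October–
December) are thought to be fueled by the nutrients those streams
delivered a year earlier. Stream gauges log discharge every 15 minutes but
suffer gaps from hours to weeks, while the lake is sampled only a few
times per season — so neither side of the relationship can be used raw.

## The model

**Stage 1 — latent discharge reconstruction.** Daily mean log-discharge
`DR = log(ζ + Q)` (offset ζ > 0 keeps zero-flow days finite; `log ζ` is
the zero-flow reference) is modelled per stream and season as

    DR_obs(t_l) = DR(t_l) + ξ(t_l),        ξ ~ N(0, σ_e²) iid
    DR(·) ~ GMRF(mean = δ0 + δ1·T(·),  precision = τR)

where `T(·)` is daily air temperature (melt tracks temperature closely)
and `R` is a sparse first-order random-walk structure matrix. The model is
fitted by a conjugate Gibbs sampler; the posterior mean curve on the full
62-node daily grid, with uncertainty, fills every gap.

**Stage 2 — scalar-on-function regression.** Each seasonal biological
response is regressed on the whole previous-season discharge curve:

    Y_i = α + Σ_j ∫₀ᵀ β_j(t) X_ij(t) dt + ε_i

with each coefficient function expanded in an orthonormal basis,
`β_j(t) = Σ_k γ_jk φ_k(t)`, and the integrals reduced to left-Riemann
quadrature scores on the shared grid. That turns the fit into an ordinary
linear model in `(α, γ)`, ridge-regularised (intercept unpenalised) with
the penalty chosen by closed-form leave-one-out cross-validation. One
single-stream model is fitted per gauged stream; their predictions are
averaged into an ensemble with ±2 SE bands, and model fit is reported as
the average of the per-model coefficients of determination (R²).

## Worked example

Simulate eight seasons of synthetic data (discharge with contiguous gaps,
temperature, depth-resolved lake profiles) and run the full pipeline:

```bash
hydrofda simulate --seed 21 --n-seasons 8 --outdir data
cat > config.yaml <<EOF
data_dir: data
outdir: out
first_discharge_season: 1994
n_seasons: 8
seed: 21
EOF
hydrofda run --config config.yaml
```

which prints

```
ppr: averaged R^2 = 95.44% (n=8)
chl: averaged R^2 = 95.21% (n=8)
```

— the ensemble-averaged in-sample R² for each biological variable over the
n = 8 usable design rows (response season s paired with reconstructed
discharge curves of season s−1). `out/summary.json` carries the full
detail; e.g. for CHL the three per-stream models reach R² of 0.98 / 0.95 /
0.92 at LOOCV-chosen ridge penalties (1, 1, 10), and the first season's
row

```json
{"season": 1995, "y": 8.77, "predicted": 8.77, "se": 0.41,
 "lower": 7.95, "upper": 9.60}
```

shows the observed response, the three-model average prediction and its
±2 SE band. `out/latents/` holds one CSV per stream-season with the
posterior mean and sd of the reconstructed log-discharge curve, and
`out/beta_*.csv` the estimated coefficient functions β_j(t).

(The high R² here reflects the synthetic generator's 3:1 signal-to-noise
ratio and in-sample evaluation at small n; real lake data sit far lower.)

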