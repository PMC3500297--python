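# stratatrend

Bayesian hierarchical spatio-temporal trend estimation for stratified
count surveys.

Long-running wildlife surveys — the motivating case is the North
American May Breeding Pair Survey of scaup, where aerial crews count
breeding pairs on 28.8-km transect segments nested in large areal
strata every year — pose three problems at once: counts are
overdispersed with excess zeros, neighbouring strata are spatially
correlated, and residuals are temporally autocorrelated. Ignoring any
of these biases the per-stratum trend estimates or overstates their
precision. `stratatrend` is for quantitative ecologists and survey
analysts who want per-stratum trends with honest uncertainty from such
data.

## The model

For count *y<sub>ijt</sub>* on segment *i*, stratum *j*, year *t*:

    y_ijt ~ ZINB(mu_jt, n, p)          (or plain NB)
    log mu_jt = alpha_j + beta_j * x_t + eta_jt + gamma_jt

* **eta** — conditional autoregressive (CAR) spatial field per year:
  each slice is Normal(0, [tau_eta (D − lam W)]⁻¹), where W marks
  stratum pairs whose centroids lie within a threshold distance
  (default: the smallest distance at which no stratum is isolated) and
  D holds W's row sums;
* **gamma** — stationary AR(1) residual series per stratum with
  autocorrelation rho and innovation precision tau_gamma (latent
  Gompertz growth on the log scale);
* **beta_j** — per-year log-scale trend for stratum *j*; a stratum is
  classified *increasing*/*decreasing* exactly when the 95% credible
  interval for beta_j excludes zero.

The posterior is sampled with a built-in adaptive
Metropolis-within-Gibbs scheme specialised to the model's sparse
structure (conjugate precision and zero-inflation updates, graph-colour
vectorised field updates, partially-collapsed hyperparameter moves);
model variants — {none, spatial, temporal, both} × {nb, zinb} — are
compared by DIC. See `docs/methods.md` for the full specification,
priors, sampler details and known limitations.

## Worked example

Simulate a survey-like dataset with two strongly declining, two
strongly increasing and four flat strata, fit the full model, and
classify the trends:

```python
import numpy as np
from stratatrend import (SimConfig, simulate_dataset, preset, fit_model,
                         SamplerSettings, classify_trends)

beta = np.array([-0.06]*2 + [0.06]*2 + [0.0]*4)
cfg = SimConfig(m=8, T=20, segments_per_stratum=25,
                alpha_values=np.full(8, 1.2), beta_values=beta,
                tau_eta=25.0, tau_gamma=25.0, rho=0.5, lam=0.5,
                p_zero=0.05, size_n=2.0, seed=11)
sim = simulate_dataset(cfg)                     # 4000 records, 20% zeros
res = fit_model(sim.counts, sim.graph, preset("both-zinb"),
                SamplerSettings(chains=2, warmup=800, draws=800, seed=1))
print(res.dic)
print(classify_trends(res).round(4).to_string(index=False))
```

Output (abridged):

```
{'Dbar': 18228.0, 'pD': 110.8, 'DIC': 18338.8}
stratum  beta_mean  beta_sd    q2.5   q97.5      class  pairs_change
     s1    -0.0507   0.0159 -0.0840 -0.0199 decreasing       -2.1746
     s2    -0.0505   0.0152 -0.0791 -0.0196 decreasing       -1.8032
     s3     0.0659   0.0168  0.0340  0.1005 increasing        7.4569
     s4     0.0903   0.0173  0.0550  0.1254 increasing       12.1190
     s5     0.0130   0.0161 -0.0178  0.0464  no_change        0.8547
     ...
```

Reading the table: `beta_mean` is the posterior mean log-scale trend
per year (s1's −0.051 ≈ −5% per year), `q2.5`/`q97.5` its 95% credible
interval, `class` the interval rule's verdict, and `pairs_change` the
posterior-mean trend-only change in mean counted pairs per segment from
the first to the last year (s4 gained ≈ 12 pairs). All four strong
strata are recovered with the correct sign; the four flat strata are
correctly left as `no_change`. `pD` is the effective number of
parameters absorbed by the latent fields.

The same pipeline is available from the shell:

```sh
stratatrend simulate --out data/ --m 52 --years 53 --unbalanced --seed 1
stratatrend fit --counts data/counts.csv --centroids data/centroids.csv \
                --preset both-zinb --out fit/
stratatrend compare --counts data/counts.csv --centroids data/centroids.csv \
                    --presets none-nb,none-zinb,temporal-zinb,both-zinb \
                    --out dic.csv
stratatrend report --fit fit/ --out report/
```

`report/` then holds `trend_table.csv` (one row per stratum, as above)
and `predictive_<stratum>.csv` posterior-predictive time series.

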