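# Methods

## The model

`stratatrend` fits a Bayesian hierarchical model to long-format counts of
breeding pairs from a stratified aerial survey: segment *i* within
stratum *j* = 1..*m* in year *t* = 1..*T* yields a non-negative count
*y<sub>ijt</sub>*.

**Data model.** Counts within a stratum-year cell are exchangeable
replicates of a common mean μ<sub>jt</sub>, observed either as

* negative binomial, NB(μ, n), in the (mean, size) parameterisation with
  variance μ + μ²/n, or
* zero-inflated negative binomial (ZINB), a mixture
  p·δ₀ + (1−p)·NB(μ, n), which accommodates the excess zeros common in
  waterfowl counts (birds present but missed, temporarily absent, or
  habitat unused — the mixture weight p absorbs both "false" and "true"
  zeros without distinguishing them per record).

The size parameter is carried on the log scale, θ = log n.

**Process model.** The log mean is additive:

    log μ_jt = α_j + β_j · x_t + η_jt + γ_jt

with x<sub>t</sub> = t − 1 (years since the first occasion, uncentered,
so α<sub>j</sub> is the first-year log mean and β<sub>j</sub> a per-year
log-scale trend). The two latent fields absorb second-order structure:

* η — spatial: each time slice η<sub>·t</sub> is a proper conditional
  autoregression (CAR) over the stratum neighbourhood graph, drawn
  independently per year with precision matrix Q = τ<sub>η</sub>(D − λW).
  W is the binary proximity matrix (centroid Euclidean distance in raw
  decimal degrees at or below a threshold; ties count), D the diagonal
  of its row sums. λ ∈ [0, 1) may be fixed or estimated; Q is strictly
  diagonally dominant, hence positive definite, whenever every stratum
  has at least one neighbour. The default threshold rule is the
  survey's: the smallest distance at which no stratum is isolated.
* γ — temporal: each stratum carries an independent stationary AR(1)
  series, γ<sub>jt</sub> = ρ·γ<sub>j,t−1</sub> + ε, ε ~ N(0, 1/τ<sub>γ</sub>),
  initialised at the stationary marginal. τ<sub>γ</sub> is the
  *innovation* precision (the marginal precision is τ<sub>γ</sub>(1−ρ²)).
  Because the residual lives on the log scale this is latent Gompertz
  growth: expected log abundance at t depends linearly on log abundance
  at t−1.

The four random-effect configurations (none / spatial / temporal / both)
crossed with the two data models give the eight named presets compared
by DIC.

**Priors** (all overridable through `PriorConfig`):

| parameter | prior | default | note |
|---|---|---|---|
| α_j, β_j | Normal | mean 0, precision 0.001 | weakly informative |
| τ_η, τ_γ | Gamma | shape 1, rate 5e-5 | conjugate; prior mean 2·10⁴ |
| θ = log n | Normal | mean 0, precision 0.01 | |
| log((1+ρ)/(1−ρ)) | Normal | mean 0, precision 0.15 | transformed scale |
| logit(λ) | Normal | mean 0, precision 0.15 | when estimated |
| p | Beta | (1, 1) | ZINB only |

The precision-0.15 priors on the transformed autocorrelation parameters
are the defaults of the latent-Gaussian framework this model family is
conventionally fit with; they are deliberately weaker than a standard
Normal so the data dominate ρ and λ.

**Identifiability.** With stratum intercepts *and* per-stratum AR(1)
residuals, the mean of each γ<sub>j·</sub> series is confounded with
α<sub>j</sub>; a soft sum-to-zero constraint (Normal prior with sd 0.2
on each series mean) pins the flat direction. The sd is intentionally
no tighter than the stationary spread of an AR(1) series mean at
moderate ρ — an over-tight constraint was found to narrow the trend
intervals below their honest width.

## Posterior computation

The sampler is an adaptive Metropolis-within-Gibbs scheme written for
the sparse structure of this model (no dense (mT × mT) matrix is ever
formed):

* **zero inflation** — per-cell structural-zero counts are drawn by
  conjugate binomial augmentation; p is then a Beta draw;
* **(α_j, β_j)** — per-stratum 2×2 adaptive random-walk blocks with a
  learned proposal covariance (α and β are strongly correlated because
  x is uncentered);
* **η** — vectorised single-site Metropolis over graph-colour classes
  (same-colour strata are non-adjacent, so their CAR full conditionals
  are independent given the rest);
* **γ** — single-site Metropolis sweeping time points sequentially with
  strata vectorised (the AR(1) conditional is Markov in t);
* **τ_η, τ_γ** — conjugate gamma full conditionals, each followed by a
  joint rescaling move (field/√c, τ·c) that traverses the
  variance funnel (without it a field initialised or driven near zero
  pins its precision at the prior scale);
* **exchange moves** — (α_j + d, γ_j − d) and (β_j + d, γ_j − d·x)
  leave every record's mean untouched, so they are accepted on a pure
  prior ratio; they decorrelate the trend from the confounded component
  of the AR(1) residuals;
* **collapsed hyper updates + exact re-split** — the likelihood sees
  only ζ = η + γ, whose marginal (split integrated out) is Gaussian
  with a Kronecker-sum covariance diagonal in the product of the CAR
  and AR(1) eigenbases. The four field hyperparameters take Metropolis
  steps against that marginal, immediately followed by an exact
  Gaussian re-split of ζ. Without this partially-collapsed step one
  field permanently absorbs the other's share — a mode trap single-site
  moves cannot escape;
* **ρ, λ, θ** — adaptive scalar random walks on transformed scales.

Proposal scales adapt by Robbins–Monro during warmup only. Chains are
seeded by spawning independent streams from one seed; identical seeds
give bitwise-identical results. Split-R̂ and effective sample size are
computed per element (via ArviZ) and reported in the summary table;
low acceptance rates and negative pD are flagged, never hidden.

**DIC** follows Spiegelhalter: D̄ is the mean posterior deviance
(evaluated through the same observation-model code the tests call
directly), D̂ the deviance at the posterior means of the quantities
entering the likelihood (per-record μ, p, θ), pD = D̄ − D̂ and
DIC = D̄ + pD. Credible intervals are equal-tailed 2.5/97.5 quantile
intervals; a stratum trend is classified increasing/decreasing exactly
when its interval excludes zero (no multiple-comparison adjustment
across strata — a deliberate caveat; the classification is a
per-stratum statement). The interval rule is computed with
inverted-CDF quantiles so that an independent tail-probability
implementation agrees with it exactly, which the code asserts on every
call.

## Synthetic data

The generator draws from the same generative model the sampler fits and
always emits the ground truth beside the data. Defaults emulate the
North American May Breeding Pair Survey design and scale: 52 strata,
53 annual occasions (1957–2009), about 50 segments per stratum-year —
in unbalanced mode as a few transects of 1–35 segments each, giving
more than 2500 segments per year — with overdispersed zero-heavy counts
(default zero-inflation 0.0204, NB size 1.5), spatial precision 81.41,
temporal precision 12.74, ρ = 0.5, λ = 0.5. Centroids are uniform in a
35° × 25° box (or a grid, or user-supplied), and the neighbour
threshold defaults to the smallest connecting distance.

What the generator does *not* emulate: observer effects and visibility
correction, the 1975 protocol change, habitat covariates, non-separable
space-time interaction, or real survey geometry. Passing recovery tests
therefore demonstrate internal consistency of model and inference, not
robustness to the mis-specification real surveys carry.

## Validation studies and scale choices

The test suite and `scripts/acceptance.py` validate the pipeline with
reduced-scale studies chosen to run comfortably on a single desktop
core; the sizes are the package's own choices:

* exact algebra (proximity/CAR/AR(1) precisions, log-determinants)
  against brute-force dense oracles on dozens of random graphs;
* likelihood normalisation by direct summation far into the NB tail;
* parameter recovery: 20 replicates at m = 8, T = 15, 10 segments per
  stratum from the full ZINB + CAR + AR(1) model (p = 0.1, ρ = 0.6,
  τ_η = τ_γ = 4, λ = 0.5, n = 2, α ~ U(0.5, 2), β ~ U(−0.04, 0.04)),
  refit with the both/zinb preset (2 chains, 1500 warmup + 1500 kept);
* DIC model recovery: 10 replicates each for ZINB-vs-NB (p = 0.3) and
  temporal-vs-none (ρ = 0.8, τ_γ = 0.7);
* trend classification: 10 replicates with 3 strongly declining,
  3 strongly increasing (|β| = 0.15/yr) and 6 flat strata;
* a survey-scale smoke run (52 × 53, unbalanced transects, short
  chains).

**Known limitation — field-split shrinkage at reduced scale.** The two
latent fields are both unstructured (m × T) effects whose *sum* alone
enters the likelihood; their decomposition is identified only through
the density ratio of their correlation structures. At the reduced
recovery scale this evidence is weak, while the Gamma(1, 5e-5)
precision prior concentrates mass at very large precisions, so the
per-dataset posterior tends to collapse one field into the other. When
the temporal field collapses, ρ reverts toward its prior; across
replicates the posterior mean of ρ is therefore shrunk noticeably
toward zero even though its 95% intervals remain calibrated (~90%
coverage in the recovery study). This is honest small-sample Bayesian
shrinkage, not a sampler artifact (long chains converge with split-R̂
≈ 1.00 and the collapse direction varies by dataset); at the full
survey scale the likelihood dominates and the effect shrinks. Users
fitting small designs should interpret the posterior *interval* for ρ,
not its point estimate, and consider tighter, substantively motivated
precision priors.

## Numerical notes

* ZINB log-probabilities combine the zero atom by log-sum-exp; counts
  up to 10⁶ and means across 1e−6..1e6 stay finite (or exactly −∞ where
  the probability is zero).
* The NB Poisson limit is verified at size 1e8 to 5e-6: beyond that,
  double-precision round-off in gamma-function differences dominates
  the analytic O(y²/n) gap.
* The CAR log-determinant uses the normalized-adjacency spectrum,
  log det(D − λW) = Σ log d_j + Σ log(1 − λv_i), computed once per
  graph.
* Degenerate inputs are rejected with descriptive errors: duplicate
  stratum ids, single-occasion designs (no trend is estimable),
  records referencing strata absent from the graph, thresholds that
  leave strata isolated (the error points at
  `min_connecting_threshold`).
* Coincident centroids are allowed (distance 0 ⇒ neighbours) with a
  warning; a stratum with no neighbour is a warning on the graph and a
  hard error only where connectivity is required (CAR, fitting).
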