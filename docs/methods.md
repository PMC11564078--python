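# Methods

## The problem

Cancer registries release small-area counts only after confidentiality
masking: any count between 1 and 5 is replaced by the token "≤5", so a
large share of the unit × disease × period panel is interval-censored.
`syndemap` implements a joint ("syndemic") disease-mapping workflow for this
setting: several diseases are modelled together over a nested areal
geography so that shared geographic risk structure is pooled across
diseases, censored cells are handled exactly rather than imputed ad hoc,
and the outputs are relative-risk surfaces, cumulative risk, pairwise
co-regionalisation, and geographic clusters.

## Model

Counts follow `Y_dit ~ Poisson(E_dit · θ_dit)` for unit *i*, disease *d*,
six-month period *t*, with the shared-component log-linear form

```
log θ_dit = α_d + x_i'β_d + δ_d φ_i + ψ_di + γ_d (t − t̄)
```

* `E_dit` — expected counts (the offset). For synthetic data the generator
  uses the true baseline rate (E = population × rate, so Y ~ Poisson(E·θ)
  exactly); for ingested real-format data without an offset column the
  package builds E by internal standardisation per disease, with censored
  cells contributing their interval midpoint.
* `φ` — the shared latent spatial field, a zero-mean Gaussian process over
  unit centroids with exponential covariance `σ²_φ exp(−h/ρ_φ)` (distances
  in km). Geostatistical covariance was chosen over CAR adjacency because
  the downstream kriging-based downscaling to fine units needs a
  continuous-space model.
* `δ_d > 0` — disease-specific loadings on the shared field, constrained to
  `Π_d δ_d = 1` (log-deltas sum to zero) so the field's scale is identified.
* `ψ_d` — disease-specific GP fields (`σ²_ψ, ρ_ψ`, optional nugget via
  `ModelSpec.psi_nugget`, default 0 — whether an extra iid heterogeneity
  term belongs in the model is genuinely open, so it is a switch, not a
  commitment).
* Time enters as a linear trend `γ_d (t − t̄)` rather than a dynamic field:
  the study design treats "time" as one candidate explanatory factor.

Priors (weakly informative defaults; `ModelSpec` exposes all of them):
`α, β, γ ~ N(0, 10²)`; `log δ ~ N(0, 1)` on the sum-zero subspace;
`σ² ~ half-Normal(0, 1)`; `ρ ~ Uniform(0.5 km, half the maximum inter-unit
distance)`. The upper ρ bound is deliberate: ranges beyond about half the
domain are indistinguishable from a constant field and only confound the
intercepts.

## Censoring

A cell is either an observed count, an integer interval `[lo, hi]`
(confidentiality censoring gives `[1, c]`, default threshold c = 5), or
missing (`[0, ∞)`, used for cross-validation hold-outs).

**Censoring reduction.** The same counts are released at sector and
district level, and sectors nest in districts, so each district total is a
sum constraint on its sectors. `integrate_nested_counts` propagates
interval bounds (`lo_i ← max(lo_i, D_lo − Σ_{j≠i} hi_j)`, symmetrically for
`hi_i`) to a fixed point and promotes point intervals to exact counts.
For a single sum constraint with interval terms this propagation yields the
exact componentwise envelope of the feasible set — verified against
exhaustive enumeration (`feasible_set_oracle`) on every small instance.
When the total is itself an interval the envelope can in principle be
looser than the true feasible set; only envelope correctness is claimed.
Infeasibility raises an error rather than repairing silently: on real data
it signals inconsistent releases.

**In the likelihood.** Remaining censored cells enter the MCMC by data
augmentation: each sweep draws the censored count exactly from
Poisson(μ) truncated to its interval by enumerating the (tiny) support —
no rejection sampling, no approximation. Likelihood-based summaries
(DIC/WAIC, predictive scores) use the interval Poisson mass
`log Σ_{k=lo..hi} Poisson(k; μ)` directly.

## Sampler

Metropolis-within-Gibbs, fully seeded and reproducible:

* imputation block (exact truncated-Poisson draws);
* per-disease `(α_d, β_d, γ_d)` random-walk Metropolis, preconditioned by
  the inverse Poisson-GLM Fisher information and step-size-adapted only
  during burn-in (target acceptance ≈ 0.3);
* `φ` and each `ψ_d` by elliptical slice sampling under their GP priors
  (the `φ` update is repeated within each sweep — the field's shape is the
  slow direction for the loadings);
* `log δ` random walk on the sum-zero subspace, interleaved with a *shear*
  move (`δ → δ'`, `ψ_d → ψ_d + (δ_d − δ'_d) φ`) that changes the loadings
  without changing the likelihood, so only the GP prior enters the
  acceptance ratio;
* likelihood-invariant *translation* moves that shift the component of a
  field lying in span{1, x_j} into the corresponding intercept or
  coefficient — these break the classic spatial-confounding slow-down;
* covariance parameters by log-scale Metropolis, plus a joint
  field/variance rescaling move that crosses the funnel between a field's
  amplitude and its variance parameter.

Exact draws from the GP conditional (kriging mean plus conditional
covariance, with coincident centroids reproduced exactly) downscale the
fields from sector to fine (LSOA-like) units.

## Variable selection

A Bayesian screen over hundreds of candidates is computationally
prohibitive, so selection uses a deterministic censored lognormal AFT
surrogate: counts are mapped to log(y+1) (interval `[1,5]` to
`[log 2, log 6]`), an observed cell contributes the normal density and a
censored cell the normal interval probability, and inference is
cluster-robust (sandwich over areal units). Search is forward-backward
stepwise on AIC (deterministic; ties break by column order), pooled across
diseases with disease indicators always retained. AIC rather than p-value
thresholds keeps the trace replayable; a p-value mode exists in
`StepwiseConfig` for sensitivity runs.

## Validation

* per-disease mean error / mean squared error of posterior-mean predictions
  (censored cells excluded by default; midpoint mode optional);
* DIC (`D̄ + p_D`, deviance conditioned on the posterior-mean intensity)
  and WAIC (`−2(lppd − p_WAIC)`) from the same retained draws;
* cell-level 10% hold-out cross-validation per disease (hold-outs become
  missing cells, which drop out of the likelihood); scores are RMSE and the
  mean squared deviation ratio MSDR = mean(err²/predictive variance),
  ≈1 when the predictive uncertainty is calibrated; unit-level hold-out is
  available via a flag;
* an independent-models baseline: one single-disease fit per disease with
  the shared component removed and the same covariates, fitted by the same
  MCMC machinery so the comparison isolates the value of sharing. Censored
  cells are midpoint-filled by default in the baseline fit; an "augment"
  mode keeps the data augmentation for like-for-like information-criterion
  comparisons.

## Post-processing

Co-regionalisation of a disease pair is summarised two ways, because both
readings of "correlation between posterior samples" are scientifically
meaningful: *pairwise* (within each draw, Pearson correlation across units
of the latent fields `δ_d φ + ψ_d`; median over draws) and *local* (within
each unit, correlation across draws). Both classify against ±0.3
(configurable). Clustering follows PCA (column-centred SVD of the
unit × disease posterior-mean log-risk matrix; raw-field mode available)
and centroid-linkage hierarchical clustering of the first two component
scores, cut at a requested cluster count — never at a merge height, since
centroid linkage can produce inversions. The number of clusters is a
config input, not auto-selected.

## Synthetic data: what it does and does not emulate

`geo_synth` generates the study-shaped structure: ~350 fine units nested in
75 sectors and 13 districts, 9 diseases over 12 six-month periods,
log-normal unit populations split into 0–50 / 50+ bands, standardized
unit-level covariates, GP shared/specific fields, Poisson counts and the
≤5 censoring rule. Default generative settings are chosen to be realistic
for the setting being emulated: base rate 1–2 per 1000 persons per
half-year (the scale of the commoner cancers), shared-field variance 0.3
with 25 km range, specific-field variance 0.1 with 10 km range (shared
structure dominant, the premise of joint modelling), covariate effects of a
few tenths on the log scale. It does **not** emulate: real geography or
road/coast structure, age-specific covariate effects, overdispersion beyond
the latent fields, reporting delay, or diagnostic (screening-driven)
artefacts — so passing recovery tests says the machinery is correct under
the stated model, not that the model is right for any particular registry.

## Numerical choices and problem sizes

Interval likelihoods are computed by log-sum-exp over the finite support;
truncated draws by Gumbel-max over enumerated support (exact). GP
factorisations add a 1e-9 diagonal jitter. PCA signs are fixed by making
each component's largest-magnitude loading positive; clustering ties break
by unit order. Tests and the acceptance script use reduced problem sizes
chosen to keep the whole suite comfortably re-runnable on one CPU
(e.g. 20 replicates of 75 × 3 × 12 panels at 8,000 MCMC iterations for the
coverage check; 30-sector panels for the cross-validation and
model-ranking replicates); these sizes are stated in the tests themselves.

## Known limitations

* δ mixes more slowly than any other parameter (it is identified only
  through the cross-disease covariance of the latent fields); the shear and
  translation moves mitigate but do not eliminate this, and the coverage
  test uses longer chains for exactly that reason.
* The binomial band in the coverage check treats intervals as independent;
  the sum-zero constraint links the D loading intervals within a replicate,
  so the band is slightly approximate.
* Bounds propagation is exact per constraint group but the joint feasible
  set across groups is not represented.
* The AFT surrogate treats counts as log-normal "times"; it is a screening
  device, not an inferential model.
* Age-band risk surfaces are produced by refitting on band-specific panels
  rather than by an age-interaction model.
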