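# syndemap

Joint Bayesian spatial mapping of multiple diseases from
confidentiality-censored areal count panels.

Small-area disease counts are routinely released with confidentiality
masking: any count between 1 and 5 appears only as "≤5". For rarer cancers
that can censor most of the map. `syndemap` is a research pipeline for
epidemiologists and health-geography analysts who want to map several
diseases *jointly* under that censoring: diseases that share geography
borrow strength from each other, and the censored cells are handled exactly
instead of being dropped or midpoint-imputed.

## The model

Counts per areal unit *i*, disease *d* and half-year period *t* follow

    Y_dit ~ Poisson(E_dit · θ_dit)
    log θ_dit = α_d + x_i'β_d + δ_d φ_i + ψ_di + γ_d (t − t̄)

a shared-component model: one latent Gaussian spatial field φ (exponential
covariance over unit centroids) is shared by all diseases through positive
loadings δ_d (constrained to Π δ_d = 1), each disease keeps a specific
field ψ_d, and x are selected area-level covariates. Censored counts are
augmented inside the MCMC with exact truncated-Poisson draws; before
fitting, interval bounds are tightened deterministically against the
district-level release of the same counts (sector counts must sum to
district totals). Post-processing yields relative-risk surfaces (sector and
kriging-downscaled fine level), cumulative risk 1 − exp(−Σ E·θ / pop),
pairwise co-regionalisation (median latent-field correlation, classified at
±0.3), and PCA + centroid-linkage geographic clusters. Validation covers
ME/MSE, DIC/WAIC, 10% hold-out cross-validation (RMSE and mean squared
deviation ratio), and an independent-models baseline with the shared
component removed.

See `docs/methods.md` for assumptions, priors, sampler design and
limitations.

## Worked example

```python
import numpy as np
import syndemap as sm

geo = sm.make_geography(n_fine=60, n_sectors=20, n_districts=4, seed=1)
cfg = sm.TruthConfig(n_covariates=2, delta=np.array([1.5, 1.0, 2/3]),
                     sigma2_phi=0.3, sigma2_psi=0.1, base_rate=2e-3)
panel, truth = sm.simulate_panel(geo, n_diseases=3, n_periods=8,
                                 truth_config=cfg, seed=2)

district = sm.aggregate_to_parent(panel, geo, "district")
cens  = sm.apply_confidentiality_censoring(panel)      # counts 1..5 -> "<=5"
dcens = sm.apply_confidentiality_censoring(district)
rec = sm.integrate_nested_counts(cens, dcens, geo)
print(f"censored {cens.n_censored}, resolved {rec.n_resolved}, "
      f"tightened {rec.n_tightened}")

spec = sm.ModelSpec(n_iter=3000, burn_in=1000, seed=3)
fit = sm.run_mcmc(rec.panel, None, geo, spec)
print("delta posterior mean:", fit.delta.mean(axis=0).round(3),
      " truth:", truth.delta.round(3))

surface = sm.summarize_risk(fit, rec.panel)
print("cumulative risk, first unit: "
      f"{surface.cumulative[0]:.4f}")
```

Output from this exact script:

```
censored 165, resolved 21, tightened 45
delta posterior mean: [1.431 1.165 0.626]  truth: [1.5   1.    0.667]
cumulative risk, first unit: 0.0344
```

Of the 165 confidentiality-censored cells, 21 are recovered exactly and 45
narrowed by reconciling against district totals; the posterior loadings
reproduce the generative ordering (disease 1 loads hardest on the shared
field, disease 3 least); and about 3.4% of the first unit's population is
expected to receive at least one of the three diagnoses over the 8 periods.

A command-line interface mirrors the stages
(`syndemap simulate | integrate | rates | select | run-all | export-maps`);
`syndemap run-all --config cfg.yaml` executes the whole pipeline and writes
a manifest that makes re-runs bit-identical.

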