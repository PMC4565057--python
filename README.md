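# betaconn

Beta-series correlation analysis of task-related functional connectivity in
event-related fMRI.

In slow event-related designs (stimulus duration longer than the TR), the
evoked response of every single trial can be estimated separately: the GLM

    Y = Xβ + ε

is fitted with one regressor per trial (a boxcar of the event duration
convolved with the canonical double-gamma HRF), alongside six motion
regressors, a 128 s discrete-cosine high-pass basis, and an AR(1) model for
serial correlations.  For each voxel (or ROI) and each experimental
condition this yields a *beta-series* — one amplitude estimate per trial.
Regions whose beta-series covary across trials are functionally connected
during that condition.  Connectivity is quantified by Pearson's (or
Spearman's) correlation r of the two series, Fisher z-transformed,

    z = ½ ln((1 + r)/(1 − r)),      SE(z) = 1/√(N − 3),

with N the number of trials per condition.  When HRF temporal and dispersion
derivatives are included, the three per-trial betas are combined into a
signed amplitude of effect, sign(β₁)·√(β₁² + β₂² + β₃²).

On top of this core the package provides, for whoever analyses event-related
fMRI at the network level:

* **seed maps** — mean seed-region beta-series correlated with every voxel,
  written as a Fisher-z NIfTI map;
* **ROI networks** — node × node Fisher-z matrices over an atlas
  parcellation (AAL-116 bookkeeping included: dropping the Cerebelum/Vermis
  labels gives the standard 90-region cerebrum network with
  n_E = n(n−1)/2 = 4005 unique edges);
* **voxel-wise degree centrality** — Dᵢ = Σⱼ bᵢⱼ and strength Sᵢ = Σⱼ wᵢⱼ of
  the thresholded voxel × voxel correlation matrix, computed by a streaming
  algorithm that never materializes the full matrix (at 70,000 voxels it
  would hold ≈2.45 billion unique entries), with a built-in sensitivity
  sweep over thresholds {0.2, 0.25, 0.3};
* **group statistics** — edgewise paired and two-sample t-tests, sign-flip /
  label-shuffle permutation tests, and Storey q-value FDR correction;
* **graph metrics** — degree, strength, betweenness, eigenvector centrality,
  clustering coefficient, characteristic path length, and hub selection
  (degree more than one SD above the mean) on the binarized network;
* **a seeded synthetic BOLD generator** — known per-trial amplitudes with a
  chosen inter-regional correlation, AR(1) noise, slow drift and motion
  confounds, so every stage can be validated against ground truth.

## Worked example

Two regions whose trial amplitudes correlate at ρ = 0.8, scanned with the
default slow event-related schedule (TR 2 s, 6 s stimulus, 10 s fixation,
3 runs × 8 trials per condition → N = 24):

```python
import betaconn as bc

spec = bc.two_region_spec(0.8, seed=42)
ds = bc.simulate_dataset(spec)
design = bc.build_design(ds.events, ds.confounds,
                         [r.n_scans for r in ds.runs], spec.tr)
est = bc.fit_glm(ds.runs, design, ds.mask)          # OLS + AR(1) prewhitening
series = bc.extract_beta_series(est, design, "emotional_single")
mat = bc.correlation_matrix(bc.roi_mean_series(series, ds.atlas))

print(f"trials per condition : {mat.n_trials}")
print(f"AR(1) coefficient    : {est.ar_coefficient:.3f}")
print(f"recovered z (1,2)    : {mat.values[0, 1]:.3f}")
print(f"true z = atanh(0.8)  : {bc.fisher_z(0.8):.3f}")
print(f"SE = 1/sqrt(N-3)     : {bc.beta_series_sem(mat.n_trials):.3f}")
```

prints

```
trials per condition : 24
AR(1) coefficient    : 0.306
recovered z (1,2)    : 0.893
true z = atanh(0.8)  : 1.099
SE = 1/sqrt(N-3)     : 0.218
```

The single-session estimate 0.893 sits within one standard error
(1/√21 ≈ 0.218) of the true Fisher z; the AR(1) coefficient recovers the
generator's ρ_noise = 0.3.  Averaged over 200 such sessions the mean
recovered z is within two standard errors of atanh(0.8) — that is exactly
what the reproduction script below measures.

The same pipeline is scriptable from the shell:

```bash
betaconn simulate --outdir raw --seed 3
betaconn fit --indir raw --outdir fitted
betaconn roi-network --indir fitted --outdir nets \
    --condition emotional_single --atlas raw/atlas
betaconn graph-metrics --matrix nets/network_emotional_single_pearson.tsv \
    --threshold 0.7 --out metrics.tsv
```

Every output file gets a JSON provenance sidecar (inputs, options, seed,
version).

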