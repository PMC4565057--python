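# Methods

This note records the models implemented in `betaconn`, the numerical
choices behind them, and what the synthetic test bed does and does not
establish about real data.

## Trial-wise GLM

The measurement model is Y = Xβ + ε per voxel.  Each trial contributes its
own regressor (least-squares-all estimation): a boxcar of the event
duration, built at microtime resolution (16 bins per TR, a boxcar of zero
duration degenerates to a unit impulse), convolved with the canonical
double-gamma HRF and sampled at the middle microtime bin of every scan.
The canonical kernel uses response delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 1/6, 32 s support, and is normalized to unit
sum; its peak sits near 5 s.  Optional basis expansion adds a temporal
derivative (backward difference against the kernel shifted by 1 s) and a
dispersion derivative (finite difference against a kernel with peak
dispersion 1.01, step 0.01, both sharing the canonical's normalization).
With derivatives enabled, the three per-trial betas collapse to the signed
amplitude sign(β₁)·√(β₁²+β₂²+β₃²); we define sign(0) = 0, so a zero
canonical beta yields a zero amplitude (the convention is arbitrary for an
event that produced no canonical response, and a signed magnitude must not
manufacture a sign from the derivatives alone).

Runs are concatenated into one model.  Per run the design carries the six
rigid-body motion parameters and a discrete-cosine high-pass block
(K = ⌊2·n·TR/cutoff + 1⌋ orthonormal columns including the constant;
default cutoff 128 s).  Filtering by inclusion in X is projection-equivalent
to pre-filtering the data and keeps the residual degrees of freedom
bookkeeping explicit.

## Serial correlations

Errors are modeled as AR(1).  The pooled estimator is the lag-1 ratio
ρ̂ = Σₜ rₜrₜ₋₁ / Σₜ rₜ², summed over all in-mask voxels with the lag never
crossing a run boundary.  Because OLS residuals are a projection P·ε of the
true errors, this raw ratio is biased toward zero — substantially so for
trial-wise designs, whose column count is a sizeable fraction of the scan
count.  `estimate_ar1` therefore accepts the design and inverts the bias by
moment matching: it solves

    observed ratio = tr(L P V(ρ) P) / tr(P V(ρ) P)

for ρ, where V(ρ) is the block-diagonal AR(1) correlation matrix and L the
within-run lag-1 operator.  `fit_glm` uses the corrected estimate, then
refits after whitening each run (y′₁ = √(1−ρ²)·y₁, y′ₜ = yₜ − ρ·yₜ₋₁,
applied identically to X).  A single global ρ is used rather than spatially
varying hyperparameters; this matches the stated AR(1) model class and
keeps the estimate stable at small mask sizes.  The whitening transform is
one-way; whitened residuals, assessed with the same corrected estimator,
are decorrelated to within sampling error.

Voxels with zero temporal variance inside the mask are flagged invalid
(NaN betas, logged) and excluded from all downstream means.  Rank-deficient
designs fall back to the pseudo-inverse with a warning.  Trial-level
quality control flags betas more than 3.5 robust SDs (1.4826·MAD) from the
median; when the MAD is zero, any deviation from the median is flagged and
an all-equal series flags nothing.

## Connectivity

All stored connectivity is Fisher z.  r is clipped to |r| ≤ 1 − 1e−7 before
atanh (z ≈ 8.4 at the clip), keeping matrices and maps finite and
NIfTI-safe.  Spearman correlations are Pearson on average-ranked data and
are z-transformed the same way, since group statistics operate on z values
regardless of the correlation flavor.  Matrices are exactly symmetrized and
the diagonal is stored as 0 and excluded from every edge statistic.  ROI
series are arithmetic means over in-mask valid voxels; empty ROIs are
dropped with a warning.  Sphere seeds include every voxel whose center lies
within the radius (inclusive).  With N trials the z values have standard
error 1/√(N−3); at the default schedule (3 runs × 8 trials per condition)
N = 24 and SE ≈ 0.218, which is why designs below ~20 trials per condition
give very noisy edges.

## Voxel-wise degree centrality

The trials × voxels beta matrix is column-standardized (mean 0, unit norm;
zero-variance columns excluded and recorded), after which Zᵀ Z is the
correlation matrix.  Degree and strength maps are computed per voxel by
streaming that voxel's correlation row in column chunks (default 2048),
Fisher-transforming, thresholding, and reducing — peak extra storage is
O(M·chunk + N) values and the N×N matrix never exists.  The result is
chunk-invariant, verified exactly against the dense computation.
Thresholds apply to Fisher-z values; the default is τ = 0.25 with a
recommended sensitivity sweep at 0.2 and 0.3 (note that z and r differ by
~6% at this magnitude, so thresholding z is the slightly stricter of the
two readings).  The default counts the positive tail only (z > τ):
anti-correlations and positive correlations should not be pooled into one
count; an absolute-value mode is available.  The self-correlation sits at
the clip boundary and is removed before counting.  The associative
shortcut S = Zᵀ(Z·1) (per-voxel sum of all correlations, self term
included) is provided for completeness but allows no thresholding or
z-transform and mixes signs; it is not used by the degree pipeline.

## Group statistics

Edgewise tests operate on the upper triangle of the z matrices: paired t on
subjectwise differences (df = n−1) and pooled-variance two-sample t
(df = n₁+n₂−2), two-sided p.  Zero-variance edges with zero mean give
t = 0, p = 1; with nonzero mean the statistic is undefined and the edge is
flagged rather than set to ±∞.  Permutation alternatives use sign-flips of
paired differences or group-label shuffles; when the full rearrangement set
fits within `n_perm` it is enumerated and p is the exact count/total
(identity included), otherwise p = (1 + hits)/(1 + n_perm), which cannot be
zero.  Storey q-values use π₀ = #{p > λ}/((1−λ)m) at λ = 0.5, floored at
1/m and capped at 1; forcing π₀ = 1 reproduces Benjamini–Hochberg exactly
(verified against statsmodels).  λ is fixed rather than smoothed — stable
at the small edge counts of ROI networks.

## Graph metrics

ROI networks are binarized at z > τ (NaN edges never survive).  Degree and
strength are row sums of the binary and thresholded weighted matrices.
Betweenness counts unordered pairs, excludes endpoints, and splits ties
equally across geodesics (computed via networkx).  Eigenvector centrality
is a shifted power iteration (A + I, which converges on bipartite graphs
where the plain iteration oscillates; tolerance 1e−10, ≤10⁴ iterations) on
the largest connected component, scaled to maximum 1, zero elsewhere.
Clustering is Cᵢ = 2·trianglesᵢ/(kᵢ(kᵢ−1)) with Cᵢ = 0 for kᵢ < 2.
Characteristic path length averages BFS distances over reachable unordered
pairs and reports the reachable fraction; an edgeless graph is an error.
Hubs are nodes with degree above mean + 1 sample SD (n−1 denominator); zero
spread means no hubs.  Metrics are cross-checked against python-igraph on
random graphs.

## Synthetic data generator

The generator mirrors the analysis forward model: per region, the signal is
the sum of trial regressors weighted by ground-truth amplitudes drawn from
a multivariate normal across regions (the covariance sets the true
inter-regional correlation); per voxel, stationary AR(1) noise (default
sd 0.5, ρ 0.3); per run, a global sinusoidal drift (default amplitude 1,
period 256 s — slow enough that the 128 s high-pass basis captures it; a
drift at exactly the 128 s band edge would leak, and because it is global
it would inflate every inter-regional correlation) and smooth random-walk
motion traces, optionally coupled into the data.  The default schedule
mirrors a slow event-related study: TR 2 s, 6 s stimulus, 10 s fixation,
3 runs, 4 conditions, 8 trials per condition per run → N = 24
betas/condition, with runs of ~528 s.  The two-region recovery spec uses
this schedule with 200-voxel regions, a realistic parcel size at 3 mm
resolution.  All draws derive from a single seed; identical specs are
bit-identical.

What the generator does **not** emulate: spatial autocorrelation and
smoothing, physiological (cardiac/respiratory) noise, hemodynamic
variability across regions, susceptibility dropout, or registration error.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to everything real data can
do; in particular, measurement noise attenuates recovered correlations
toward zero (visible in the validation suite only as a small fraction of
the standard error under these conditions), and any global artifact the
filter fails to remove inflates them.

## Validation problem sizes

The validation suite runs at desk scale, chosen to keep the full suite in
the low minutes: streaming-versus-dense equivalence at M = 24 × N = 500
over 10 seeds, chunk ∈ {1, 7, 500} and τ ∈ {0.2, 0.25, 0.3}; the recovery
study at 200 replicates of the two-region session; the null calibration of
the paired t at 500 replicates of 12 subjects × 36 edges; graph metrics on
20 random graphs of up to 30 nodes.  The AAL and 160-node fixtures use the
real label tables over synthetic low-resolution label volumes (deterministic
nearest-centroid parcellations of an ellipsoid), so region counts and
name-based bookkeeping are faithful while anatomical locations are not; the
160-node fixture's coordinates are synthetic and are labeled as such.

## Known limitations

* Least-squares-all only; no least-squares-separate variant for fast
  designs, where trial regressors collinearity makes LSA fragile.
* One global AR(1) coefficient; no spatial variation, no higher-order AR.
* Binary graph metrics only (weighted strength aside); no community
  detection; no voxel-level betweenness/clustering/path length.
* Group inference is edgewise with FDR; no cluster-level or random-field
  corrected map statistics.
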