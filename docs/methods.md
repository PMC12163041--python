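# Methods

`topobrain` extracts topological signatures from per-region brain activity
time series and evaluates what those signatures carry about individuals:
identity (cross-session fingerprinting), a binary group label, and behavior
(supervised prediction and canonical correlation with permutation
inference). This note records the models, the numerical choices, and the
limits of what the synthetic cohort can demonstrate.

## Pipeline

For each (subject, session, ROI) series `x(t)`:

1. **Bandpass (optional, default on).** Zero-phase 4th-order Butterworth,
   0.01–0.08 Hz, applied forward–backward (`sosfiltfilt`), the conventional
   resting-state fMRI band. Sampling rate defaults to 1/0.72 s.
2. **Delay embedding.** `x` is mapped to the point cloud with rows
   `(x_i, x_{i+τ}, …, x_{i+(m−1)τ})`. One *global* (τ, m) pair is used for
   the whole dataset so that embedded geometry is comparable across
   subjects: per-series estimates on a random subsample (default 12
   series) are aggregated by the median, rounded up.
   - τ: first local minimum of the lagged mutual information
     (equal-width 16-bin 2-D histogram, nats). The raw MI profile jitters
     lag-to-lag at realistic sample sizes, which creates spurious shallow
     minima; the scan therefore runs on a centered moving average of the
     profile (width 7, configurable). If no local minimum exists the
     global minimum is used and a warning issued.
   - m: smallest dimension whose false-nearest-neighbor fraction drops
     below 2%, with the classical tolerances r_tol = 15 and a_tol = 2.
     Neighbor pairs whose extra-coordinate gap is below 1e−8 of the series
     scale are counted as true neighbors: exact revisits of a periodic
     orbit otherwise produce ratio-test artifacts on denormal-scale
     numbers.
3. **Vietoris–Rips persistence (H0, H1).** A simplex enters the filtration
   at its longest pairwise distance (closed threshold; lexicographic tie
   order). H0 is computed by union-find over distance-sorted pairs: the
   finite deaths are exactly the minimum-spanning-tree edge weights, and
   the essential component is capped at `max_eps` (default: cloud
   diameter) so the landscape transform sees finite bars. H1 comes from
   GF(2) column reduction of the edge/triangle boundary matrix in
   filtration order (numba-compiled; reduced columns stored in a flat
   pool). Two exact accelerations: the filtration is truncated at the
   enclosing radius, beyond which the complex is a cone and has no
   1-cycles; and edge columns are never reduced because union-find already
   settles dimension 0. Zero-persistence H1 bars are discarded. Clouds
   larger than a landmark budget (pipeline default 40) are first reduced
   by maxmin (farthest-point) selection from a seeded start; at 40
   landmarks the dominant loop structure of the embedded orbits is
   preserved while keeping the cohort-scale H1 cost at ~10 ms per cloud.
   A brute-force full-matrix reduction lives in the test suite as an
   independent oracle; the two implementations agree endpoint-for-endpoint
   on random clouds.
4. **Persistence landscapes.** A diagram point (b, d) contributes the tent
   `max(0, min(t−b, d−t))`; layer k is the k-th largest tent value. Each
   diagram is sampled on a uniform grid from 0 to the maximum death
   observed across the whole collection, one grid per homology dimension,
   persisted and reused verbatim for held-out data — cross-subject
   comparisons need a common basis. The default discretization is 5
   layers × 20 bins = 100 values per (ROI, dimension); 1 × 100 is
   available. Subject vectors concatenate ROI-major, H0 before H1, layer,
   then bin: 200 ROIs give 200 × 100 × 2 = 40 000 features.
5. **Temporal baseline.** 22 classical time-series statistics spanning
   autocorrelation structure, distribution shape, frequency content,
   nonlinearity and stationarity — mirroring the domains of the canonical
   22-feature catalogue — plus the raw mean and standard deviation
   (population convention) appended last: 24 per ROI. The 22 shape
   statistics are computed on an internally z-scored copy, so scale
   information enters only through the last two slots. Undefined values
   propagate as NaN and are median-imputed per feature at the cohort
   level.

## Downstream analyses

- **Fingerprinting.** Each session-2 vector is matched to the most
  Pearson-correlated session-1 vector; accuracy is the fraction of
  self-matches. No column normalization is applied (Pearson is invariant
  to per-vector affine maps). Ties break toward the smallest index and are
  flagged. Per-network scores rerun the matching on one network's feature
  columns.
- **CCA.** Behaviors are filtered (missingness > 10%, variance < 1e−12, or
  a single value covering > 95% of subjects drop an item), residualized on
  confounds (intercept always included), z-scored and reduced by PCA; the
  features likewise. The first canonical correlation is the largest
  singular value of `Qx' Qy` for orthonormal bases of the two PC score
  matrices — verified against scikit-learn's NIPALS CCA in the tests.
  Significance: subject rows of the behavioral PC matrix are permuted
  (freely — synthetic subjects are exchangeable), r1 recomputed, and
  p = (1 + #{r_perm ≥ r1}) / (1 + n_perm), whose floor at 10 000
  iterations is 1e−4. Interpretation uses structure loadings
  (item–variate correlations) rather than raw weights; per-ROI
  contributions correlate each ROI block's sign-aligned first PC with the
  canonical feature variate, and |H0| vs |H1| contributions are compared
  per network by a two-sample t-test.
- **Supervised harnesses.** Binary classification: L2 logistic regression
  (C = 1), stratified 5-fold, one ROC/AUC from pooled out-of-fold
  probabilities. Regression: linear model, 5-fold repeated 10 times with
  different splits, one Pearson r (predicted vs observed) per repeat.
  z-scoring and PCA are fit inside each training fold — fitting them once
  globally would leak held-out statistics into training, so the
  reduce-then-validate ordering is deliberately rejected. Two feature
  sets evaluated with the same seed share fold splits, which is what makes
  the per-repeat paired t-test valid.

## Synthetic cohort

Each subject i carries a latent z_i ∈ R^5 that simultaneously drives the
dynamics, a binary group g = 1{w·z > 0}, and behaviors Y = C z + η (C and
w are fixed unit-norm constants independent of the cohort seed, so the
planted association strength is a model property, not a seed property).
Per ROI r the signal is a two-harmonic oscillator

    x(t) = g_s · [ a sin(2π f_s t + φ_s) + h sin(4π f_s t + ψ_s) ] + ε(t)

with per-(subject, ROI) parameters mapped from the latent through
affine-then-tanh functions plus idiosyncratic components drawn once per
subject: amplitude a ∈ [0.55, 1.45], harmonic amplitude h ∈ [0.05, 0.75],
relative phase δ = ψ₀ − 2φ₀ ∈ (−π, π), ROI base frequencies spread over
0.025–0.065 Hz (harmonics partly attenuated by the 0.08 Hz band edge,
as in real data). The second harmonic is essential: a pure sinusoid
embeds to an ellipse for every subject, while the harmonic term gives the
orbit a subject-specific loop geometry. Sessions share all subject-level
parameters and differ by i.i.d. Gaussian noise (sd 0.3), phase jitter
(0.05 rad), and a 4% frequency drift; an optional multiplicative
amplitude drift and a slow within-scan envelope modulation exist in the
model but default to zero. The idiosyncratic parameter components make
individuals identifiable beyond what the 5-dimensional latent allows —
with 50 subjects in a 5-dimensional latent space, nearest-neighbor
collisions would otherwise cap fingerprint accuracy well below its
empirical value.

Desk-scale defaults (50 subjects, 20 ROIs, 300 timepoints, TR 0.72 s,
40-landmark H1) keep a full cohort run around half a minute on one CPU;
the acceptance script averages planted-effect metrics over 5 cohort
replicates and the test suite over 20.

**Planted association strength.** The behavioral noise default (0.75)
plants a first canonical correlation of ≈0.95 between latents and
behaviors (`planted_canonical_correlation` computes the exact value). A
planted value of 0.70 — realistic for large cohorts — is not reliably
detectable by a 10-PC permutation CCA at n = 50; the association is
scaled up as the cohort is scaled down so that the detection claim, not
the effect size, is what the test exercises.

## What the synthetic cohort does and does not show

The generator reproduces the qualitative structure of the reference
findings: landscape features are far better cross-session fingerprints
than the temporal baseline (≈0.99 vs ≈0.84 here), the planted group and
behavior are recoverable from topological features, and the permutation
machinery is calibrated (null CCA p uniform, permuted-label AUC at 0.5,
paired-t size nominal).

It does **not** demonstrate superiority of topological over temporal
features for *classification*. Persistence diagrams are isometry
invariant, so every property a scalar oscillator can vary is either
visible to both feature families (amplitude and harmonic content through
variance, kurtosis and spectral statistics; phase through third-moment
statistics) or visible to neither (purely time-asymmetric structure).
On this generator the two feature sets classify the planted group at
statistically indistinguishable AUC (0.80 vs 0.83 across 20 cohorts,
the baseline marginally ahead).
The fingerprinting contrast survives because identification is an
unnormalized correlation match, where the landscape's scale-equivariant,
highly redundant encoding of amplitude is genuinely more stable than a
24-statistic summary — but a claim that loop geometry *per se* carries
unique information would need richer-than-oscillator dynamics. Real fMRI
also has spatial correlation, hemodynamic filtering, non-Gaussian noise
and family structure, none of which are modeled.

## Degenerate inputs and conventions

Constant series raise a degenerate-input error in delay selection and are
flagged (features zeroed, std = 0) in the temporal baseline; constant
feature vectors get −∞ similarity in fingerprinting. Clouds with fewer
than three points have empty H1. Duplicate points yield zero-persistence
H0 bars, which are kept; zero-persistence H1 bars are dropped. The paired
t-test pins its degenerate cases: identical inputs give (0, 1), a
constant nonzero difference gives (±inf, 0) with a warning. All
randomness flows from explicit seeds; the pipeline derives per-stage
seeds from one master seed by SHA-256 of "seed:stage".
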