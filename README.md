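# topobrain

Topological signatures of brain dynamics. `topobrain` turns per-region
(ROI) brain activity time series into geometric objects — each ROI's
signal is delay-embedded into a state-space point cloud, summarized by
Vietoris–Rips persistent homology in dimensions 0 (components) and 1
(loops), and vectorized as persistence landscapes — and then asks what
those topological feature vectors carry about individuals:

- **Fingerprinting**: can a person be identified across scanning sessions
  by correlating their feature vectors?
- **Group classification**: cross-validated logistic regression / ROC-AUC
  on a binary label (a gender analog in the synthetic cohort).
- **Behavior**: repeated cross-validated regression of behavioral scores,
  and a first-mode canonical correlation analysis (CCA) between features
  and a behavioral battery with permutation inference.

A conventional 24-features-per-ROI temporal baseline (22 classical
time-series statistics plus mean and standard deviation) is built in for
comparison. The package targets researchers who want to evaluate
topological representations of dynamics on their own ROI×time matrices,
and ships a fully planted synthetic cohort generator so every claim is
testable without any restricted dataset.

## The core objects

For a series `x(t)` the delay embedding is the cloud
`X = {(x_i, x_{i+τ}, …, x_{i+(m−1)τ})}` with delay τ (first local minimum
of lagged mutual information) and dimension m (false-nearest-neighbor
criterion). The Vietoris–Rips filtration includes a simplex when all its
pairwise distances are within ε; sweeping ε yields persistence diagrams
{(bᵢ, dᵢ)} per homology dimension. Each diagram point contributes the tent
function Λᵢ(t) = max(0, min(t − bᵢ, dᵢ − t)), and the landscape layer
λ_k(t) is the k-th largest tent value at t. Landscapes are sampled on a
shared grid (default 5 layers × 20 bins = 100 values per ROI and
dimension) and concatenated into one vector per subject-session — with
200 ROIs, 200 × 100 × 2 = 40 000 features.

H0 is computed by union-find (finite deaths = minimum-spanning-tree edge
weights); H1 by numba-compiled GF(2) boundary-matrix reduction, checked
in the test suite against an independent brute-force full reduction.

## Worked example

```python
import dataclasses
from topobrain import generate_cohort, identify
from topobrain.pipeline import (RunConfig, compute_diagrams,
                                compute_embedding_params,
                                landscape_features, temporal_feature_matrix,
                                _preprocess, _session_split)

cfg = RunConfig(landmarks=40, seed=1)
cohort = generate_cohort(dataclasses.replace(cfg.cohort, seed=1))
series = _preprocess(cohort.series, fs=1 / 0.72, band=cfg.band)
params = compute_embedding_params(series, cfg)
print("embedding:", params)

diagrams = compute_diagrams(series, params, cfg)
pl, keys, layout, grids = landscape_features(diagrams, cfg)
tmp, tkeys = temporal_feature_matrix(series)
pl1, pl2, _ = _session_split(pl, keys)
t1, t2, _ = _session_split(tmp, tkeys)
print("landscape fingerprint:", identify(pl1, pl2).accuracy)
print("temporal  fingerprint:", identify(t1, t2).accuracy)
```

prints

```
embedding: EmbeddingParams(delay=8, dimension=3)
landscape fingerprint: 1.0
temporal  fingerprint: 0.84
```

— on this 50-subject synthetic cohort the automatic selection selects a
delay of 8 samples and an embedding dimension of 3; matching session-2 to
session-1 landscape vectors identifies every subject, while the temporal
baseline identifies 42 of 50. The identity signal the generator plants in
each subject's oscillation amplitudes and loop geometry is preserved by
the topological summary across session noise, phase jitter and frequency
drift, and only partly by the 24 per-ROI statistics.

The same objects feed the rest of the analyses, e.g. first-mode CCA
against the behavioral battery:

```python
from topobrain import cca_first_mode, deconfound, filter_behaviors
Y, kept = filter_behaviors(cohort.behaviors)
res = cca_first_mode(pl1, deconfound(Y.to_numpy()), n_pc=10,
                     n_perm=999, seed=1)
print(round(res.r1, 3), res.p_perm)   # -> 0.92 0.001
```

The permutation p-value has floor 1/(n_perm + 1): 0.001 at 999
iterations, 0.0001 at 10 000.

## Command line

```
topobrain simulate --config cohort.yaml --out DIR     # write a cohort as TSVs
topobrain ph       --in DIR --tau auto --dim auto --out diagrams.tsv
topobrain baseline --in DIR --out temporal.tsv
topobrain fingerprint --day1 f1.tsv --day2 f2.tsv --out result.json
topobrain all      --config config.yaml --out RUNDIR  # full pipeline + manifest
```

Input layout: one `sub-<i>_ses-<s>.tsv` per subject-session (rows = ROIs,
columns = timepoints), plus `networks.tsv`, `behaviors.tsv`, `groups.tsv`.
Any dataset in this layout works; nothing is specific to the synthetic
generator.

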