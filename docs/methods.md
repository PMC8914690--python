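# Methods

This note documents the models, conventions and numerical choices behind
`grasptex` in enough detail to reproduce or audit every stage.

## Problem and pipeline shape

The package classifies six basic grasp types — cylindrical (C), hook (H),
lateral (L), palmar (P), spherical (S), tip (T) — from two-channel
surface-EMG trials sampled at 500 Hz (5–6 s per trial). It is a
hand-crafted learning network, not a deep model: features are engineered,
selection is explicit, classification is shallow. The stages are

1. channel concatenation: `sEMG = [ch1, ch2]`;
2. multi-parameter tunable-Q wavelet decomposition into 153 subbands;
3. per-source feature extraction (raw signal + each subband): 384 texture
   features from the frustum-graph ternary pattern plus 30 statistical
   moments = 414 features per source, 154 sources;
4. column-wise min–max normalisation per source;
5. loss generation: each source's 414-feature matrix is scored by
   stratified 10-fold cross-validated misclassification with both a
   1-NN(L1) and a cubic-SVM classifier; the family with the lower mean
   loss across sources is kept (greedy model selection);
6. the 20 lowest-loss sources are concatenated (8280 columns);
7. iterative NCA refines this to the loss-minimising prefix of the
   NCA weight ranking, sweeping sizes 100–512;
8. final stratified 10-fold cross-validated evaluation.

The pipeline is exposed statsmodels-style: `GraspModel(dataset, config)`
with `fit()` returning a `GraspResults` that carries every intermediate
product and a `summary()` table; `run_pipeline` is the functional wrapper
and the CLI sits on top of both.

## Frustum-graph ternary pattern

Each stride-1 window of 49 samples is reshaped **row-major** into a 7×7
matrix. Three fixed 6-edge directed graphs are drawn on the grid — the
bottom hexagon of a frustum, its top hexagon, and the six connecting
edges. For every directed edge (a → s) the signed difference a − s is
compared against a global ternary threshold d = std(signal)/2: the
"upper" kernel emits 1 iff a − s > d, the "lower" kernel emits 1 iff
a − s < −d; boundary cases (a − s = ±d) emit 0 in both. The six bits of
one graph/kernel combination, weighted least-significant-first
(bit j → 2^(j−1)), give a code in [0, 63]; per combination, the 64-bin
histogram over all windows is taken, and the six histograms are
concatenated in the order bottom-1, bottom-2, top-1, top-2,
connection-1, connection-2 (384 features).

Conventions the source material leaves open, fixed here:

- **Fill order** of the 49 samples into the 7×7 matrix: row-major.
  Any fixed order is internally consistent; row-major matches the
  natural index iteration.
- **Threshold scope**: d is computed once from the whole input signal or
  subband, not per window.
- **Standard deviation**: sample convention (n−1), configurable via the
  `ddof` argument of `compute_threshold`. Only codes with differences
  exactly at ±d can change under the population convention.
- **Histogram order**: the kernel-major order above; the construction
  fixes the set of six histograms but not their order.

Consequences used as test oracles: every histogram sums to len−48; codes
are 6-bit; the features are invariant under x → a·x + b for a > 0
(differences and threshold scale together); negating the signal swaps
the two kernels of each graph.

## Statistical features

Fifteen moments — mean, median, variance, Shannon entropy, log-energy
entropy, maximum, minimum, standard deviation, range, SURE entropy,
kurtosis, skewness, Higuchi fractal dimension, energy, root mean
square — evaluated on the raw samples and again on |x| (30 values, in
that frozen order). Choices:

- Entropies use the wavelet-coefficient (unnormalised, squared-
  coefficient) family, appropriate for wavelet subbands:
  Shannon = −Σ x²ln x² (0·ln 0 := 0), log-energy = Σ ln x² (ln 0 := 0),
  SURE = n − #{|x| ≤ ε} + Σ min(x², ε²) with ε = 3 by default.
- Kurtosis is Pearson (non-excess; normal → 3), skewness the population
  third standardised moment; both 0 for constant input.
- Variance/std use the sample (n−1) convention.
- Higuchi fractal dimension: curve lengths over decimated sub-series for
  k = 1..kmax (default 10), offsets averaged, slope of ln L(k) vs
  ln(1/k) by least squares; a constant signal returns 1.0 by convention.
  Verified limits: ramp ≈ 1, white noise ≈ 2. Inside
  `statistical_features`, kmax is clipped to n−1 so very short subbands
  remain processable; the standalone `higuchi_fd` errors instead.
- "Root mean square error" is read as the signal RMS — no reference
  signal exists in this context.

## Tunable-Q wavelet transform

The TQWT is implemented in its original radix-free frequency-domain
form: per level, a unitary-DFT spectrum of length M maps to a low-pass
band of length N0 = 2·round(α^j·N/2) and a high-pass band of
N1 = 2·round(β·α^(j−1)·N/2), with β = 2/(Q+1), α = 1 − β/r, transition
bands weighted by the Daubechies response
θ(ω) = (1 + cos ω)·√(2 − cos ω)/2. Because θ(ω)² + θ(π − ω)² = 1 the
bank is a Parseval tight frame: perfect reconstruction and exact energy
conservation hold (observed at machine precision; tested at the 1e−8 /
1e−6 tolerances). Details:

- Rounding is MATLAB-style half-away-from-zero, forced even at every
  level; lengths are computed from the original N, not iteratively.
- The admissibility limit J_max(N) = ⌊ln(βN/8)/ln(1/α)⌋ is enforced with
  an error naming both J and J_max.
- Odd-length inputs are zero-padded by one sample (recorded on the
  `SubbandSet`, undone on synthesis). Both study trial lengths (6000 and
  5000 after concatenation) are even, so this never triggers on the
  real data.
- Conjugate symmetry is imposed explicitly at each level, so subbands
  are exactly real.
- Synthesis applied to coefficient vectors *outside* the analysis range
  (e.g. a low-pass band with details zeroed) is non-expansive but not
  isometric — a property of any oversampled tight frame; energy equality
  holds only for passband content. The tests assert exactly this.

The four parameterizations (Q, r, J) = (1,2,6), (2,4,24), (3,6,46),
(4,8,73) yield 7 + 25 + 47 + 74 = 153 subbands for a 6000-sample input,
each set ordered detail level 1..J then the final low-pass.

Subbands shorter than 49 samples cannot support a texture window; they
are zero-padded to 49 for the texture half (statistical half uses the
raw band) and a warning is logged once. On the study's signal lengths
every band is ≥ 50 samples, so this only concerns scaled-down inputs.

## Subband selection

Normalisation is per-feature (column-wise) min–max over observations,
the standard reading; constant columns map to 0. A per-matrix variant is
available behind `per_matrix_normalization` for sensitivity analysis.
Normalisation precedes loss generation (the pipeline's stage order).

Loss generation scores all 154 normalised sources with both classifier
families under the same seeded stratified folds; ranking uses the
chosen family's per-source losses with ties broken toward the smaller
source id. Note the published procedure selects inside the same
cross-validation universe used for final evaluation — this is
reproduced faithfully; it is an optimistic protocol, and users who need
leakage-free estimates should hold out data before `fit()`.

## NCA and the iterative selector

The feature-selecting (diagonal) NCA maximises the leave-one-out soft
nearest-neighbour objective with the weighted L1 distance
d_ij = Σ_l w_l²|x_il − x_jl| (matching the pipeline's 1-NN metric),
soft-neighbour probabilities p_ij ∝ exp(−d_ij/σ), and ridge penalty
λ‖w‖² with λ = 1/n by default. Choices where the source material is
silent:

- **Kernel length-scale σ**: defaults to the mean pairwise L1 distance
  at unit weights. Without it the softmax saturates once the feature
  count is large (distances grow linearly in p) and gradients vanish;
  scaling by the data's own distance scale keeps the objective
  responsive at p = 8280 as well as p = 10. Configurable.
- **Optimiser**: deterministic full-batch gradient ascent from an
  all-ones weight vector, step normalised by the gradient's max-norm,
  backtracking halving with mild re-growth, 100 iterations by default.
  The whole INCA stage is therefore a pure function of the seed (which
  governs the CV folds).
- The iteration range [100, 512] is swept with stride 1 by default
  (configurable for speed); the range is clipped to [1, p] when p is
  smaller, and the loss-minimising prefix wins with ties toward the
  smaller size. A conflicting statement in the source description
  ("chooses 413 features") is treated as a typo for the 414-length
  per-source vector; the tabulated range is authoritative.

## Classifiers and metrics

- 1-NN, Manhattan distance, no distance weighting.
- Cubic SVM: kernel (1 + ⟨u, v⟩)³ after dividing features by the
  "auto" kernel scale, C = 1, one-vs-one. The auto scale is an
  environment-specific heuristic in the original setting; here it is
  the median pairwise L1 distance of a seeded subsample of at most 1000
  points (an approximation, fixed-scale override available). One-vs-one
  vote ties resolve toward the lowest class index.
- Stratified 10-fold CV, fold assignment a pure function of the seed.
- Metrics from the 6×6 confusion matrix (rows true, columns predicted,
  order C,H,L,P,S,T): recall = 100·TP/row, precision = 100·TP/col
  (0 with a warning for an empty column), F1 their harmonic mean,
  overall accuracy = 100·trace/n, and **macro** (unweighted) averages
  for the aggregate precision/recall/F1 — on the balanced benchmark
  datasets macro and support-weighted means agree to rounding.

## Synthetic data

`synth_dataset` emulates what the pipeline needs from sEMG without any
download: each class is an order-4 autoregressive process (two conjugate
resonator pole pairs, radius 0.95) driven by unit-variance Gaussian
innovations under a class-scaled Hann amplitude envelope — i.e.
amplitude-modulated colored noise, the standard phenomenological sEMG
model. Class k places its resonances at 30 + 12k·separation Hz and
90 + 16k·separation Hz (separation = 1 by default), with amplitude
1 + 0.2k. Defaults follow the study's recording conditions: 500 Hz,
6 s per trial, 30 trials per class per subject-equivalent.

What it does **not** emulate: motor-unit action-potential shapes,
electrode crosstalk, inter-subject variability, day-to-day drift, or
movement artefacts. A green end-to-end test therefore establishes that
the pipeline's machinery is correct and discriminates spectrally/
amplitude-coded classes — not that real-data accuracies are reproduced.
Real-data replication lives in `examples/replicate_uci.py` and requires
the public download.

Scaled-down test runs use 2 s trials (1 s for CLI smoke tests) to stay
inside CI budgets; the generator defaults remain the stated 6 s.

## Known limitations

- Loss-based source selection and INCA both see the full labeled
  dataset (the published protocol); reported CV accuracies are
  optimistic relative to nested CV.
- NCA hyperparameters (λ, σ, iterations) influence the ranking; the
  defaults are documented above but were not tuned against real data.
- The v7.3 MAT reader handles plain numeric variables only (sufficient
  for the public dataset's layout).
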