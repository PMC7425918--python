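# Methods

This note documents the models, conventions and numerical choices behind the
`msfs` package: a multi-stage feature-selection (MSFS) pipeline for
classifying breast-tumor size from forward-scattered ultra-wideband (UWB)
signals, together with a synthetic phantom-signal simulator that stands in
for the (undeposited) physical measurements.

## The problem and the pipeline

A UWB pulse centered at 4.3 GHz is transmitted through a breast phantom and
recorded on the opposite side (1632 samples per acquisition).  A tumor
inserted in the phantom perturbs the received signal in a size- and
location-dependent way.  The task is six-class classification: no tumor, or
a tumor of 2, 3, 4, 5 or 6 mm.

The MSFS procedure turns raw signal sets into a small, strongly
class-separating feature matrix in four stages:

1. **Normalization bank + PCA elimination.**  Ten normalizations are applied
   to the raw amplitudes; each normalized dataset is projected onto its
   principal components and trailing components are dropped until a
   matrix-level one-way ANOVA across the size classes reaches p < 0.05.
2. **Feature extraction.**  Ten scalar features per record: standard
   deviation (SD), mean (M), variance (V), skewness (S), Shannon entropy
   (SE), leading independent component (ICA), SURE entropy (SU), mean Welch
   power spectral density (PSD), and the max (MAX) / min (MIN) of the
   magnitude spectrum.
3. **Statistical selection.**  One-way ANOVA F and p across size classes
   select the 5 best normalization methods (matrix-level test) and then the
   10 best feature–method combinations (column-level test), under the rule
   "p < 0.05, then highest F".
4. **Fusion.**  The rank-ordered feature columns are fused into hybrid
   datasets of width m; repetition blocks are collapsed to one SVD
   representative per acquisition configuration; F is scanned for
   m = 10 … 2 and the three best widths go to classification.

Classification uses a one-vs-rest linear SVM (C = 1), Gaussian naive Bayes,
and a probabilistic neural network (spread 0.1), under seeded stratified
10-fold cross-validation, with the rank-1 single feature as the reference
dataset.

## The synthetic phantom simulator

The measurement campaign that motivates this package was never deposited, so
`msfs.phantom` generates signal sets that follow the same acquisition
protocol and possess the statistical structure the downstream stages assume.
It is a statistical stand-in, not an electromagnetic solver.

Signal model for one record (all defaults in `AcquisitionConfig`):

    r(t) = g_d · p(t − τ_d) + g_e·s² · p(t − τ_e(x)) + d(t) + n(t)

- `p(t)` — Gaussian-modulated sinusoid, carrier 4.3 GHz, envelope sigma
  0.25 ns, centered 3 ns into a 16.32 ns window sampled at 1632 points
  (100 GS/s).  The window and rate are package conventions (the protocol
  fixes only the sample count); they put the 4.3 GHz content far below
  Nyquist and give ~61 MHz FFT resolution.
- Direct path: gain `g_d` = 0.5, delay `τ_d` from the 10 cm transmitter–
  receiver separation at 10 cm/ns (≈ c/3, relative permittivity ≈ 9,
  tissue-mimicking).
- Tumor echo: amplitude `g_e·s²` with `g_e` = 0.01 and `s` the tumor size in
  mm — a cross-section-like scaling law that makes echo amplitude strictly
  increasing in size; delay `τ_e` follows the Euclidean detour
  transmitter → tumor → receiver, so it is monotone in path length.
  Size 0 (tumor-free) has no echo term.
- Baseline drift `d(t)`: a deterministic 0.1-period sinusoid of amplitude
  0.05 across the window, identical for every record.  Because it is
  systematic, subtracting the tumor-free reference removes it exactly —
  which is precisely the failure mode the five reference-based
  normalizations exist to correct.
- Noise `n(t)`: i.i.d. Gaussian, sd 0.01 per sample.

Default protocol: 5 sizes × 27 locations × 50 repetitions = 6750 tumor
records plus 750 tumor-free records appended last (7500 total), ordered
size-major, then location, then repetition.  The 27 locations are the
3 × 3 × 3 subgrid x, y ∈ {0.25, 3.25, 6.25} cm, z ∈ {3, 4, 5} cm of the
printed coordinate values.  Everything is reproducible from `rng_seed`.

What the simulator does **not** emulate: multipath and dispersion, antenna
coupling, tissue heterogeneity, amplitude dependence on tumor location, and
measurement-session drift variation.  Passing tests on synthetic data
therefore demonstrate that the pipeline recovers a size-dependent scattering
structure it is designed for — not that the published real-data accuracies
are reproduced.  The chosen echo/noise scales give a strongly separable
task (per-record echo SNR well above 1 after matched filtering), so
cross-validated accuracies near the ceiling are expected; the informative
comparisons are hybrid-vs-reference and hybrid-vs-chance.

## Conventions and numerical choices

**Normalizations.**  The five relative ("voltage") methods are defined in
`msfs.normalization` (module docstring) — element-wise, dimension-preserving
and reference-based; the reference is the element-wise mean of the tumor-free
records.  ZS uses per-signal statistics while MSD uses dataset-global
statistics (otherwise the two would coincide).  All moments use the
population (1/N) convention.  Divisions and logarithms carry an additive
guard ε = 1e-12.  Logarithms in RLV/RLSSV are base 10 (voltage-ratio
convention).  Constant signals under ZS/MM either return zeros with a
warning or raise, per the `degenerate_policy` switch.

**PCA elimination.**  "Last column" means the lowest-variance component
(PCA columns are variance-ordered).  Component signs are fixed by making the
largest-magnitude loading positive.  The significance test is the same
matrix-level ANOVA used in stage 3, for internal consistency.  The loop
tests the current width before each drop, so an already-significant input is
returned untouched; the floor is `min_components` (library default 1;
pipeline default 2 so per-record score vectors stay long enough for the
moment features).  The pipeline caps the fitted basis at 20 components
(`pca_components`): the simulated signals are low-rank (pulse, echo, drift)
plus white noise, so 20 components capture essentially all structured
variance while keeping the elimination loop short.

**Features.**  Row-wise features are computed on each record's retained
PCA-score vector; PSD/MAX/MIN are computed on the full-length normalized
signal (spectra of PC scores carry no frequency meaning).  Shannon entropy
uses the energy distribution p_i = v_i²/Σv² in nats (the raw
−Σ v·log v form is undefined for negative amplitudes).  SURE entropy is
Σ min(v_i², ε²) with ε chosen by exact minimization of Stein's unbiased risk
of soft thresholding over the candidate set {0} ∪ {|v_i|}, noise scale from
MAD/0.6745.  Welch PSD: Hamming window, segment length 256, 50 % overlap,
density scaling, fs = 1, scalarized as the mean over bins.  ICA: FastICA on
the whole matrix, seeded with a fixed iteration cap; since FastICA orders
components arbitrarily, the "leading" component is the most non-Gaussian one
(largest |excess kurtosis|), sign-fixed to positive skew; non-convergence
falls back to the first principal component with a warning.

**Selection.**  The matrix-level (F, p) of a feature matrix is the one-way
ANOVA of the per-record mean of column-standardized features; a
mean-of-column-F heuristic is available behind `matrix_statistic(mode=
"mean_f")`.  `select_top` filters p < α, then sorts by F descending with a
*stable* sort: exactly tied F values keep their enumeration order (in the
published worked example this places V-RV ahead of SU-RV, matching the
published ranking).  Both selection analyses run on the tumor records only
(five size classes); tumor-free records join at classification.

**Fusion.**  A repetition block's rank-1 SVD of its one-column matrix is
σ·u with σ = ‖b‖; its scalar representative is sign(mean b)·rms(b), with +
when the mean is exactly 0.  The default protocol collapses 6750 records to
135 configuration rows (5 sizes × 27 locations).  Classification uses the
per-record fused matrix; the hybrid F-evaluation uses the collapsed matrix —
the only consistent reading of the two printed dimensions in the source
procedure.  Hybrids are rank-prefixes only; other column subsets are out of
scope.

**Classification and metrics.**  Folds are stratified and seeded; when a
class has fewer members than k, the planner falls back to plain shuffled
folds with a warning.  Features are standardized with training-fold
statistics inside each fold (this keeps the PNN spread of 0.1 meaningful
across datasets of different scales).  The PNN score is computed in log
space (log-sum-exp), so tiny spreads degrade gracefully to nearest-pattern
behavior instead of underflowing; ties resolve to the lower class label.
Metrics follow the tumor-screening reading of TP/TN: the tumor-free class is
negative; TP = tumor record assigned its exact size, FN = tumor record
assigned any wrong class, TN/FP from the tumor-free row.  Accuracy is then
(TP+TN)/total — identical to the confusion-matrix trace over total — and
sensitivity/specificity are TP/(TP+FN) and TN/(TN+FP), reported per fold and
averaged.  A macro-averaged one-vs-rest convention was considered and
rejected: it is inconsistent with the screening definitions of TP/TN above
(e.g. it would give ≈ 72 % "accuracy" to random guessing on six balanced
classes, where the screening convention correctly gives ≈ 16.7 %).

## Problem sizes used by the test and acceptance runs

Unit and property tests run on small synthetic instances (tens to hundreds
of records, 64–256 samples) generated at test time.  The statistical
calibration suite uses 1000 null ANOVA simulations, 200 power simulations at
δ = 1 (n = 300), and 20 chance-level cross-validation runs (n = 600).  The
recovery experiment and the acceptance script run the full default protocol
(7500 records × 1632 points) end to end — about one minute on one CPU.

## Known limitations

- The simulator's echo law and geometry are declared conventions; no claim
  of electromagnetic fidelity is made, and real-data accuracies are neither
  targeted nor reproduced.
- The matrix-level (F, p) summary of a feature matrix is this package's
  definition; the source procedure does not specify one.
- The PNN spread is fixed at 0.1 (no tuning), the SVM is linear with C = 1,
  and naive Bayes is parameter-free, mirroring the fixed-parameter design.
- Feature selection applies no multiple-testing correction, by design.
- With ten identical-quality informative columns the hybrid-width scan can
  prefer narrow widths on synthetic data; the scan reports all nine widths
  so this is visible in the run report.
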