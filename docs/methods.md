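# Methods

## Signal model and feature pipeline

The package targets multichannel EEG epochs `x_c(t)`, `c = 1..C`
channels, sampled at `fs = 200` Hz and cut into non-overlapping 3-s
windows (600 samples), each carrying one emotion label in {1, 0, −1}
(positive / neutral / negative).  Continuous recordings are first
bandpass-filtered to 0.1–46 Hz with a zero-phase 4th-order Butterworth
(applied forward–backward, so the effective magnitude response is
squared; a 60 Hz tone is attenuated ≈ 31 dB).

### Discrete S-transform

For an epoch of `N` samples the transform is computed per channel in the
FFT domain (the classical formulation): for each analysis frequency `f`
the spectrum is shifted by `f`, multiplied by the real Gaussian voice
window `G_f(ν) = exp(−2π²ν²·width²/f²)` and inverse-transformed.
Conventions, all of which tests pin down:

- **Frequency grid**: the DFT bins of the epoch (multiples of
  `1/duration`, i.e. 1/3 Hz for 3-s epochs) clipped to `[fmin, fmax]` =
  [0.1, 46.0] Hz; zero frequency excluded.  `fmax` must be below
  Nyquist.
- **No zero padding**: the transform is circular in time, which makes
  coefficient magnitudes exactly invariant under integer circular shifts
  of a periodic input and keeps pure on-grid tones free of edge
  transients.
- **Normalization**: `G_f(0) = 1`, i.e. each voice's time window
  integrates to one.  The defining marginal identity
  `Σ_τ S(τ, f) = X(f)` then holds exactly, and is asserted to 1e−6
  relative in the tests (it is machine-precision in practice).
- **width** (default 1, the classical transform) scales the temporal
  window std as `width/f`; the frequency-domain std is `f/(2π·width)`.

One consequence worth knowing: Gaussian voices are wide at high
frequency (σ_ν ≈ 4.6 Hz at 29 Hz), so strong content just above a band
edge leaks into the band below it.  In the synthetic classification
example the Beta band (12–30 Hz) partially picks up a Gamma-band
(30–46 Hz) effect this way.

### Band grouping

Coefficient magnitudes `|S|` are averaged over the frequency bins of
each band — full (0.1–46), Delta (0.1–4), Theta (4–8), Alpha (8–12),
Beta (12–30), Gamma (30–46 Hz) — with half-open intervals
`[low, high)` except the last band (closed), so shared edges are never
double-counted.  The mean (not the sum) is used so that band width does
not scale the series.

### Sliding differential entropy

Under a local Gaussian model, differential entropy has the closed form
`h = ½·ln(2πe·σ²)` (natural log; all internal values are nats).  For a
series of length `N` and window width `k` (stride 1) the package
computes the population variance (divide by `k`, the plug-in estimate
matching the Gaussian model; a `sample` estimator is available) of each
of the `N − k + 1` windows and applies the formula.  The variance is
floored at `ε = 1e−12` so constant windows — which genuinely occur for
pure tones, whose S-transform magnitude is constant in time — produce a
finite value instead of −∞.  Key identities, enforced as property
tests: adding a constant leaves the entropy sequence unchanged; scaling
the series by `c > 0` shifts it by exactly `ln c`.

Window widths of interest are `k ∈ {5, 10, 20}` samples (25–100 ms at
200 Hz).

### CSP on entropy sequences

Each epoch's channel × position entropy matrix `E` is summarized by the
*uncentered* second-moment matrix `E·Eᵀ/T`, trace-normalized, then
averaged per class.  Uncentered moments matter here: the discriminative
signal of a band-variance effect lives in the per-channel entropy
*level* (log local amplitude), which row-centering would erase; with
uncentered covariances classical CSP recovers it.  The generalized
eigenproblem `C_a w = λ(C_a + C_b) w` is solved with
`scipy.linalg.eigh`; the 4 eigenvectors with the largest and 4 with the
smallest `λ` (default `n_components = 8`) are kept, ordered by
descending eigenvalue, each row's first non-negligible coefficient
forced positive.  A rank-deficient composite covariance is
ridge-regularized (`δ = 1e−8·trace/C`) with a warning.  Features are the
classical normalized log variances
`ln(var(Z_j)/Σ_m var(Z_m))`, `Z = W·E`, so `Σ exp(feature) = 1`.

Three-class problems use one-vs-rest CSP (one model per class against
the pooled rest, features concatenated, 3 × 8 = 24); with only two
classes present this degenerates to the single binary model.  The
literature does not single out one multiclass CSP construction;
one-vs-rest was chosen as the simplest scheme that preserves the binary
machinery.

### Evaluation protocols

Stratified 5-fold cross-validation and a stratified 80/20 holdout, both
seeded.  CSP is fitted inside each training fold/split only; a
`csp_within_folds=False` audit mode exists solely to let tests verify
that fitting on all data (leakage) would not *lower* accuracy.
Classifiers are fixed — RBF-SVM (`C = 20`, `gamma = 'scale'`) and
random forest (256 trees) — with no tuning loop.

## Synthetic data

`EmotiveEEGSpec` defaults define the simulated study conditions:
62 channels, 60 epochs per class, 200 Hz, 3-s epochs.  Every epoch is
independent `1/f^α` Gaussian background (α = 1, unit variance per
channel — an EEG-like spectral slope) plus brick-wall band-limited
Gaussian noise in the class band (default Gamma, 30–46 Hz) with
standard deviation 1.5 on all channels; on the epoch's class-specific
effect channels (disjoint 8-channel subsets per class by default) the
band-noise variance is multiplied by `effect_gain` (default 6).  With
`effect_gain = 1` the classes are statistically identical — the null
used to verify that the pipeline reports chance accuracy.

What the generator emulates: the dimensions, sampling, labels, spectral
slope and band-limited class structure of emotion EEG.  What it does
not: volume conduction (channels are independent), artifacts,
non-stationarity within epochs, inter-subject variability, and any
actual neurophysiology of emotion.  Passing tests therefore demonstrate
that the pipeline recovers band-localized variance structure from
realistic-looking noise — not that it recognizes emotions in real
recordings.

Deterministic signals (`SignalSpec`) cover pure sines, linear chirps
(phase `φ(t) = 2π(f0·t + (f1−f0)t²/(2D))`), and sample-wise linear
amplitude ramps; generation is reproducible bit-for-bit from the recipe
(including its seed, for the randomized family).

## The swept-signal study and its calibration

The study quantifies entropy stability: for a unit sine at `f` Hz
(one 3-s epoch at 200 Hz, matching the pipeline's epoch length), compute
the S-transform, reconstruct the waveform of the band containing `f` by
remodulated voice summation (`Σ_f Re[S(τ,f)·e^(j2πfτ)]` over the band's
bins, closed interval — the published grid assigns edge frequencies like
12 Hz to the band that contains them as an upper edge), then take the
sliding differential entropy and report the standard deviation of the
resulting sequence.

Two conventions are deliberate calibration points, fixed once against
the Delta-band 1 Hz anchor row of the published grid and then left
alone:

- **Aggregation rule.**  The entropy of the study is computed on the
  band *waveform* (voice summation), not on the magnitude envelope.
  For an on-grid in-band tone the reconstruction is exactly
  `c·sin(2πft)` for a constant `c`, so the statistic is independent of
  the window details and of `c` (log-scale equivariance); this rule
  reproduces the published grid's strong frequency dependence, which no
  envelope-based rule does (a tone's magnitude envelope is nearly
  constant, and its entropy std neither falls with frequency nor spans
  the published range).  The classification pipeline keeps the
  magnitude-envelope rule of `band_group`; for broadband EEG both carry
  the same band-level information and the envelope is the conventional
  choice there.
- **Reporting unit.**  The published standard deviations are reproduced
  cell-for-cell when entropy is expressed in units of
  `ENTROPY_UNIT = 0.05` nat (equivalently, a logarithm of base
  `e^(1/20)`); the defining formula writes `log` without a base.  All
  internal computation is in nats; only the study module rescales.

With these two choices the regenerated 15 × 3 grid matches the
published one to ≤ 2% in every cell except the 0.04-unit cell (≈ 5%,
print-precision limited), including the printed exact zero at
(30 Hz, k = 20): a 20-sample window spans exactly three periods of a
30 Hz tone at 200 Hz, so every window sees the same sample multiset and
the entropy sequence is constant.

The mechanism behind the grid: the sliding entropy of a sampled tone is
`ln σ_local` across the cycle; for `f·k/fs ≥ 1` each window covers a
full period and `σ_local` is constant, while for small `f` windows near
the peaks have variance orders of magnitude below windows at the zero
crossings, so the entropy sequence swings through tens of units.
Consequently the std decreases with frequency, decreases with window
width, and stabilizes across window widths at high frequency — the
three qualitative trends the study turns into statements about why
Gamma-band features classify well.

## Numerical choices and problem sizes

- Variance floor 1e−12 (see above); population variance estimator.
- Sliding-window variance is evaluated per epoch/row so the strided
  window views never materialize multi-gigabyte temporaries.
- CSP eigenvalues are clipped to [0, 1] against floating-point
  excursions; filters' sign convention makes fits reproducible.
- The end-to-end recovery experiment in the test suite uses the
  generator defaults (62 channels, 60 epochs/class, Gamma gain 6); the
  null-control experiment uses 24 channels and 30 epochs/class, sizes
  chosen to keep those checks proportionate to what they assert (a
  joint chance-level check needs fewer samples than an accuracy
  ordering).  The null check compares each band's CV accuracy against
  the Bonferroni-adjusted family-level 95% binomial interval of chance,
  since six bands are tested jointly.

## Known limitations

- The S-transform is circular (no padding): epochs containing strong
  transients at their boundaries wrap around.  For 3-s EEG epochs after
  bandpass filtering this is negligible in practice.
- Independent-channel synthetic data cannot probe CSP's behaviour under
  realistic spatial mixing; the toy covariance tests cover the algebra
  instead.
- `read_session` reads MATLAB v7 containers (the common SEED format);
  v7.3/HDF5 files are out of scope.
- Entropy features are scale-free by construction (log variance), so a
  uniform per-channel gain change is invisible to centered statistics;
  the pipeline relies on uncentered CSP moments for exactly this
  reason.
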