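# stentropy

Stockwell-entropy and common-spatial-pattern (CSP) feature extraction for
multichannel EEG emotion recognition.

EEG correlates of emotional state are strongest in high-frequency (Gamma,
30–46 Hz) oscillations, but raw band power is noisy and spatially mixed.
This package implements a feature pipeline that addresses both problems:

1. **Stockwell (S-)transform** — each 3-s epoch of each channel is
   decomposed into complex time–frequency coefficients
   `S(τ, f) = ∫ x(t) w(τ−t) e^(−j2πft) dt` with a Gaussian window `w`
   whose temporal width scales as `1/f` (fine time resolution at high
   frequency, fine frequency resolution at low frequency).
2. **Band grouping** — coefficients are grouped into the six analysis
   bands: full (0.1–46 Hz), Delta (0.1–4), Theta (4–8), Alpha (8–12),
   Beta (12–30) and Gamma (30–46 Hz).
3. **Stockwell entropy** — each band series is tracked with sliding-window
   Gaussian differential entropy, `h = ½·ln(2πe·σ²)` per window of
   `k ∈ {5, 10, 20}` samples: a log-variance measure of local signal
   complexity.  A sequence of length `N` yields `N − k + 1` entropy values.
4. **CSP** — the per-epoch entropy sequences are spatially filtered by
   solving `C_a w = λ (C_a + C_b) w` for the class covariance matrices;
   the 8 extreme eigenvectors give normalized log-variance features.
5. **Classification** — RBF-SVM (`C=20, gamma='scale'`) or random forest
   (256 trees), evaluated with stratified 5-fold cross-validation or an
   80/20 holdout; CSP is refitted inside every training fold so no test
   information leaks into the spatial filters.

A synthetic-data module generates both the deterministic test signals of
the accompanying frequency/amplitude study (sines, 0–46 Hz chirps,
amplitude ramps) and randomized three-class multichannel datasets
(1/f background plus class-dependent band-limited variance), so the full
pipeline is testable without any EEG download.  SEED-style MATLAB v7
sessions are supported via `stentropy.io.read_session`.

## Worked example

`examples/emotion_classification.py` generates a 16-channel, 45-epoch
three-class dataset whose classes differ only in Gamma-band variance on
disjoint channel subsets, and cross-validates the pipeline per band:

```
  band window  pos/neg  3-class
 gamma      5     1.00     1.00
 gamma     20     1.00     1.00
  beta      5     1.00     1.00
  beta     20     1.00     1.00
 delta      5     0.67     0.49
 delta     20     0.70     0.47
```

The Gamma band, which carries the planted effect, is classified
perfectly at every window width; the Delta band, with no effect, stays
at chance level (0.5 binary / 0.33 ternary, n = 30/45 epochs).  Beta
also separates here because the Gaussian voices of the S-transform near
30 Hz leak some of the 30–46 Hz effect into the Beta rows.

`examples/swept_signal_study.py` prints the entropy-stability grid for
unit sines at the band-edge frequencies (std of the sliding-entropy
sequence, in the study's reporting units of 0.05 nat):

```
 band  frequency  std_w5  std_w10  std_w20
delta       1.00   16.63    15.44    13.68
alpha       8.00   11.37     7.34     1.88
 beta      13.00    8.95     3.75     0.59
gamma      41.00    0.23     0.22     0.21
gamma      45.00    0.93     0.64     0.04
```

(excerpt).  Entropy of low-frequency tones fluctuates wildly — a
5-sample window at 200 Hz sees only a sliver of a 1 Hz cycle, so the
local variance spans orders of magnitude across the cycle — while above
30 Hz every window covers a full cycle and the std drops below one unit.
This temporal stability is why Gamma-band entropy features classify well.

`examples/csp_spatial_filters.py` shows CSP recovering the closed-form
solution of a two-channel toy problem (eigenvalues exactly 10/11, 1/11).

## Command line

```sh
stentropy synth --channels 62 --epochs-per-class 60 --gain 6 --seed 1 --out session.npz
stentropy extract --input session.npz --band gamma --window 20 --out features.csv
stentropy classify --features features.csv --clf svm --mode cv5 --seed 1
stentropy simstudy --table2 --out grid.csv
```

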