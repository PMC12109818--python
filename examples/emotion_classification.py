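"""Classify synthetic three-class "emotive EEG" with Stockwell entropy + CSP.

Generates a compact 16-channel dataset whose classes differ only in
Gamma-band (30-46 Hz) variance on disjoint channel subsets, extracts
sliding-entropy features per band, and runs stratified 5-fold CV with an
RBF-SVM (CSP refitted inside each training fold -- no leakage).

Expected outcome: near-perfect accuracy in the Gamma band (where the
class effect lives), chance-level accuracy in the Delta band (no
effect), and stability across sliding-window widths.
"""

import numpy as np

from stentropy import (
    ClassifierSpec,
    EmotiveEEGSpec,
    ExtractionConfig,
    band_series_tensors,
    crossval,
    entropy_from_series,
    make_emotive_dataset,
)

spec = EmotiveEEGSpec(n_channels=16, n_epochs_per_class=15, effect_gain=6.0, seed=7)
epochs = make_emotive_dataset(spec)
labels = np.array([ep.label for ep in epochs])
print(
    f"{len(epochs)} epochs of {spec.n_channels} channels x "
    f"{int(spec.epoch_len * spec.fs)} samples; Gamma variance gain "
    f"{spec.effect_gain} on per-class channel subsets\n"
)

series = band_series_tensors(epochs, ExtractionConfig())
clf = ClassifierSpec()  # RBF-SVM, C=20, gamma='scale'

print(f"{'band':>6} {'window':>6} {'pos/neg':>8} {'3-class':>8}")
for band in ("gamma", "beta", "delta"):
    for k in (5, 20):
        ent = entropy_from_series(series[band], k)
        binary = crossval(ent, labels, (1, -1), clf, seed=0, band=band, window_k=k)
        ternary = crossval(ent, labels, (1, 0, -1), clf, seed=0, band=band, window_k=k)
        print(f"{band:>6} {k:>6} {binary.mean:8.2f} {ternary.mean:8.2f}")

print(
    "\nAccuracies are stratified 5-fold CV means; 0.5 / 0.33 are the binary"
    "\nand ternary chance levels.  The Gamma band carries the planted effect."
)
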