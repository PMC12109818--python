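"""End-to-end orchestration: preprocessing, epoching, feature
extraction per band, and the two evaluation protocols.

The feature path per epoch is

    bandpass 0.1-46 Hz -> S-transform -> band magnitudes ->
    sliding differential entropy (window k) -> CSP -> log-variance
    features -> SVM / random forest,

with CSP fitted inside each training fold only (stratified 5-fold CV)
or on the training split of an 80/20 holdout, so no information from
the evaluation epochs leaks into the spatial filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .csp import csp_features, fit_csp, fit_multiclass, multiclass_features
from .entropy import sliding_de
from .stockwell import DEFAULT_BANDS, Band, SignalEpoch, band_group, stransform

__all__ = [
    "ExtractionConfig",
    "ClassifierSpec",
    "CVReport",
    "FeatureTable",
    "preprocess",
    "epoch_split",
    "band_series_tensors",
    "entropy_from_series",
    "band_entropy_tensors",
    "extract_features",
    "crossval",
    "holdout_eval",
    "make_classifier",
]


@dataclass
class ExtractionConfig:
    """Feature-extraction parameters (defaults follow the study protocol)."""

    epoch_len: float = 3.0
    fmin: float = 0.1
    fmax: float = 46.0
    width: float = 1.0
    bands: tuple[Band, ...] = DEFAULT_BANDS
    window_k: int = 20
    n_csp: int = 8

    def __post_init__(self) -> None:
        if self.window_k < 2:
            raise ValueError(f"window_k={self.window_k} must be >= 2")
        if self.n_csp < 2 or self.n_csp % 2:
            raise ValueError(f"n_csp={self.n_csp} must be a positive even number")


@dataclass
class ClassifierSpec:
    """Classifier hyperparameters (fixed; no tuning loop)."""

    kind: str = "svm_rbf"  # or "random_forest"
    C: float = 20.0
    gamma: str = "scale"
    n_trees: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "random_forest"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class CVReport:
    """Accuracy report for one task x band x window combination."""

    task: tuple
    band: str
    window_k: int
    clf: str
    mode: str  # "cv" or "holdout"
    seed: int
    fold_accuracies: list[float]
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        accs = np.asarray(self.fold_accuracies, dtype=float)
        if accs.size == 0 or np.any((accs < 0) | (accs > 1)):
            raise ValueError("fold accuracies must be non-empty and in [0, 1]")
        self.mean = float(accs.mean())
        self.std = float(accs.std())


@dataclass
class FeatureTable:
    """Per-epoch CSP log-variance features ready for a classifier."""

    X: np.ndarray  # (n_epochs, n_features)
    y: np.ndarray  # (n_epochs,), labels in {1, 0, -1}
    band: str
    window_k: int


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator described by a spec."""
    if spec.kind == "svm_rbf":
        return SVC(C=spec.C, kernel="rbf", gamma=spec.gamma)
    return RandomForestClassifier(n_estimators=spec.n_trees, random_state=spec.seed)


def preprocess(recording: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.1-46 Hz bandpass (4th-order Butterworth, filtfilt).

    Expects 200 Hz data (warns otherwise).  Raises if the recording is
    shorter than the filter warm-up needs.
    """
    recording = np.atleast_2d(np.asarray(recording, dtype=float))
    if fs != 200.0:
        warnings.warn(f"expected fs=200 Hz, got {fs}", stacklevel=2)
    sos = butter(4, [0.1, 46.0], btype="bandpass", fs=fs, output="sos")
    pad = 3 * (2 * sos.shape[0] + 1)
    if recording.shape[-1] <= pad:
        raise ValueError(
            f"recording too short for zero-phase filtering: need more than "
            f"{pad} samples, got {recording.shape[-1]}"
        )
    return sosfiltfilt(sos, recording, axis=-1)


def epoch_split(
    recording: np.ndarray, fs: float, epoch_len: float, label: int | None
) -> list[SignalEpoch]:
    """Cut a continuous recording into non-overlapping labeled epochs.

    Windows are ``round(epoch_len * fs)`` samples long; a trailing
    remainder shorter than one epoch is dropped.
    """
    recording = np.atleast_2d(np.asarray(recording, dtype=float))
    n = int(round(epoch_len * fs))
    n_epochs = recording.shape[-1] // n
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.shape[-1]} samples shorter than one "
            f"epoch ({n} samples)"
        )
    return [
        SignalEpoch(
            data=recording[:, i * n : (i + 1) * n].copy(),
            fs=fs,
            label=label,
            t0=i * n / fs,
        )
        for i in range(n_epochs)
    ]


def band_series_tensors(
    epochs: Sequence[SignalEpoch], cfg: ExtractionConfig
) -> dict[str, np.ndarray]:
    """Per-band magnitude series ``(n_epochs, n_channels, N)``.

    This is the expensive stage (one S-transform per epoch); compute it
    once and reuse it across window widths, tasks, folds and classifiers.
    """
    out: dict[str, list[np.ndarray]] = {b.name: [] for b in cfg.bands}
    for ep in epochs:
        tfr = stransform(ep, fmin=cfg.fmin, fmax=cfg.fmax, width=cfg.width)
        bs = band_group(tfr, cfg.bands)
        for i, b in enumerate(cfg.bands):
            out[b.name].append(bs.values[:, i, :])
    return {name: np.asarray(rows) for name, rows in out.items()}


def entropy_from_series(series: np.ndarray, k: int) -> np.ndarray:
    """Sliding differential entropy along the last axis of a band tensor.

    Computed epoch by epoch to bound the memory of the sliding-window
    variance temporaries.
    """
    series = np.asarray(series)
    if series.ndim <= 2:
        return sliding_de(series, k)
    return np.stack([sliding_de(ep, k) for ep in series])


def band_entropy_tensors(
    epochs: Sequence[SignalEpoch], cfg: ExtractionConfig
) -> dict[str, np.ndarray]:
    """Per-band entropy tensors ``(n_epochs, n_channels, N - k + 1)``."""
    return {
        name: entropy_from_series(series, cfg.window_k)
        for name, series in band_series_tensors(epochs, cfg).items()
    }


def _labels_of(epochs: Sequence[SignalEpoch]) -> np.ndarray:
    labels = [ep.label for ep in epochs]
    if any(lab is None for lab in labels):
        raise ValueError("all epochs must be labeled")
    return np.asarray(labels, dtype=int)


def _fit_and_featurize(
    entropy: np.ndarray,
    y: np.ndarray,
    task: Sequence[int],
    n_csp: int,
    fit_idx: np.ndarray,
    band: str | None = None,
):
    """Fit CSP on ``fit_idx`` epochs only; featurize all epochs."""
    task = list(task)
    if len(task) == 2:
        a, b = task
        models = [
            fit_csp(
                entropy[fit_idx][y[fit_idx] == a],
                entropy[fit_idx][y[fit_idx] == b],
                n_csp,
                class_pair=(a, b),
                band=band,
            )
        ]
    else:
        by_label = {
            lab: entropy[fit_idx][y[fit_idx] == lab] for lab in task
        }
        models = fit_multiclass(by_label, n_csp, band=band)
    if len(models) == 1:
        X = np.array([csp_features(models[0], e) for e in entropy])
    else:
        X = np.array([multiclass_features(models, e) for e in entropy])
    return X, models


def extract_features(
    epochs: Sequence[SignalEpoch],
    cfg: ExtractionConfig,
    task: Sequence[int] = (1, 0, -1),
    fit_idx: Sequence[int] | None = None,
) -> dict[str, FeatureTable]:
    """CSP log-variance features for every band.

    ``fit_idx`` restricts CSP fitting to a training subset (evaluation
    protocols must pass one to avoid leakage); by default the filters
    are fitted on all provided epochs, which is only appropriate when
    the output is not re-used for accuracy estimation.
    """
    y = _labels_of(epochs)
    mask = np.isin(y, list(task))
    tensors = band_entropy_tensors([e for e, m in zip(epochs, mask) if m], cfg)
    y = y[mask]
    fit = np.arange(len(y)) if fit_idx is None else np.asarray(fit_idx, dtype=int)
    tables = {}
    for name, ent in tensors.items():
        X, _ = _fit_and_featurize(ent, y, task, cfg.n_csp, fit, band=name)
        tables[name] = FeatureTable(X=X, y=y, band=name, window_k=cfg.window_k)
    return tables


def crossval(
    entropy: np.ndarray,
    y: np.ndarray,
    task: Sequence[int],
    clf: ClassifierSpec,
    *,
    n_folds: int = 5,
    seed: int = 0,
    n_csp: int = 8,
    band: str = "",
    window_k: int = 0,
    csp_within_folds: bool = True,
) -> CVReport:
    """Stratified k-fold cross-validation on one band's entropy tensor.

    CSP is fitted inside each training fold only (``csp_within_folds``
    exists solely as a leakage audit: setting it False fits the filters
    on all epochs, test folds included, and must not decrease accuracy).
    """
    y = np.asarray(y, dtype=int)
    mask = np.isin(y, list(task))
    entropy, y = entropy[mask], y[mask]
    counts = [int((y == lab).sum()) for lab in task]
    if min(counts) < n_folds:
        raise ValueError(
            f"smallest class has {min(counts)} epochs; need >= n_folds={n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(entropy, y):
        fit = np.arange(len(y)) if not csp_within_folds else train
        X, _ = _fit_and_featurize(entropy, y, task, n_csp, fit, band=band)
        est = make_classifier(clf)
        est.fit(X[train], y[train])
        accs.append(float(est.score(X[test], y[test])))
    return CVReport(
        task=tuple(task),
        band=band,
        window_k=window_k,
        clf=clf.kind,
        mode="cv",
        seed=seed,
        fold_accuracies=accs,
    )


def holdout_eval(
    entropy: np.ndarray,
    y: np.ndarray,
    task: Sequence[int],
    clf: ClassifierSpec,
    *,
    test_fraction: float = 0.2,
    seed: int = 0,
    n_csp: int = 8,
    band: str = "",
    window_k: int = 0,
) -> CVReport:
    """Single stratified train/test split (default 80/20)."""
    y = np.asarray(y, dtype=int)
    mask = np.isin(y, list(task))
    entropy, y = entropy[mask], y[mask]
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    X, _ = _fit_and_featurize(entropy, y, task, n_csp, train, band=band)
    est = make_classifier(clf)
    est.fit(X[train], y[train])
    acc = float(est.score(X[test], y[test]))
    return CVReport(
        task=tuple(task),
        band=band,
        window_k=window_k,
        clf=clf.kind,
        mode="holdout",
        seed=seed,
        fold_accuracies=[acc],
    )
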