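"""Common spatial patterns over per-epoch entropy sequences.

CSP finds channel-weight vectors w maximizing the variance ratio
between two trial classes.  With class covariance matrices C_a and C_b
this is the generalized eigenproblem

    C_a w = lambda (C_a + C_b) w,    lambda in [0, 1],

whose extreme eigenvectors concentrate variance in one class or the
other.  Covariances here are *uncentered* second-moment matrices
(E E^T / T), trace-normalized per epoch before class averaging; the
entropy sequences fed to CSP carry class information in their per-channel
levels (log local amplitude), which centering would discard.

Feature extraction follows the classical recipe: project an epoch onto
the retained filters and take the normalized log variance of each
component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh

__all__ = [
    "CSPModel",
    "fit_csp",
    "csp_features",
    "fit_multiclass",
    "multiclass_features",
    "save_model",
    "load_model",
]


@dataclass
class CSPModel:
    """Fitted spatial filters for one class pair (or one-vs-rest)."""

    filters: np.ndarray  # (n_components, n_channels)
    eigenvalues: np.ndarray  # (n_components,), descending, in [0, 1]
    n_components: int
    class_pair: tuple = (None, None)
    band: str | None = None

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]


def _epoch_cov(epoch: np.ndarray) -> np.ndarray:
    e = np.asarray(epoch, dtype=float)
    if e.ndim != 2 or e.shape[1] < 2:
        raise ValueError("each epoch must be a (channels, T>=2) matrix")
    cov = e @ e.T / e.shape[1]
    tr = np.trace(cov)
    if tr <= 0:
        raise ValueError("epoch has zero total power")
    return cov / tr


def _mean_cov(epochs: Sequence[np.ndarray]) -> np.ndarray:
    covs = [_epoch_cov(e) for e in epochs]
    if not covs:
        raise ValueError("empty epoch list")
    return np.mean(covs, axis=0)


def fit_csp(
    epochs_a: Sequence[np.ndarray],
    epochs_b: Sequence[np.ndarray],
    n_components: int = 8,
    *,
    class_pair: tuple = (None, None),
    band: str | None = None,
) -> CSPModel:
    """Fit CSP filters discriminating two sets of (channels x T) epochs.

    The ``n_components/2`` eigenvectors with the largest and the
    ``n_components/2`` with the smallest generalized eigenvalue are
    retained, rows ordered by descending eigenvalue; each filter's first
    non-negligible coefficient is forced positive for reproducibility.

    Raises
    ------
    ValueError
        On empty inputs, channel mismatch, or invalid ``n_components``
        (must be even and at most the channel count).
    """
    C_a = _mean_cov(epochs_a)
    C_b = _mean_cov(epochs_b)
    if C_a.shape != C_b.shape:
        raise ValueError(
            f"channel mismatch: {C_a.shape[0]} vs {C_b.shape[0]} channels"
        )
    n_ch = C_a.shape[0]
    if n_components % 2 != 0 or not 0 < n_components <= n_ch:
        raise ValueError(
            f"n_components={n_components} must be even and in [2, {n_ch}]"
        )

    composite = C_a + C_b
    eigvals = np.linalg.eigvalsh(composite)
    if eigvals[0] <= 1e-10 * max(eigvals[-1], 1e-30):
        delta = 1e-8 * np.trace(composite) / n_ch
        composite = composite + delta * np.eye(n_ch)
        warnings.warn(
            f"rank-deficient composite covariance; ridge-regularized with "
            f"delta={delta:.3e}",
            stacklevel=2,
        )

    lam, vecs = eigh(C_a, composite)
    order = np.argsort(lam)[::-1]
    lam, vecs = lam[order], vecs[:, order]
    half = n_components // 2
    pick = np.r_[np.arange(half), np.arange(n_ch - half, n_ch)]
    filters = vecs[:, pick].T.copy()
    for row in filters:
        nz = np.flatnonzero(np.abs(row) > 1e-12 * np.abs(row).max())
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return CSPModel(
        filters=filters,
        eigenvalues=np.clip(lam[pick], 0.0, 1.0),
        n_components=n_components,
        class_pair=class_pair,
        band=band,
    )


def csp_features(model: CSPModel, epoch: np.ndarray) -> np.ndarray:
    """Normalized log-variance features of one epoch.

    Projects ``Z = filters @ epoch`` and returns
    ``log(var(Z_j) / sum_m var(Z_m))`` per component (uncentered
    variance, matching the covariance definition used in fitting), so
    ``sum(exp(features)) == 1``.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[0] != model.n_channels:
        raise ValueError(
            f"epoch has {epoch.shape[0]} channels, model expects {model.n_channels}"
        )
    z = model.filters @ epoch
    var = (z * z).mean(axis=-1)
    total = var.sum()
    if total <= 0:
        raise ValueError("degenerate epoch: zero total variance after projection")
    return np.log(var / total)


def fit_multiclass(
    epochs_by_label: dict[int, Sequence[np.ndarray]],
    n_components: int = 8,
    *,
    band: str | None = None,
) -> list[CSPModel]:
    """One-vs-rest CSP models for a multiclass problem.

    With exactly two classes present this reduces to a single binary
    model; otherwise one model is fitted per class against the pooled
    remaining classes, in label order 1, 0, -1.
    """
    labels = [lab for lab in (1, 0, -1) if lab in epochs_by_label]
    labels += sorted(set(epochs_by_label) - set(labels))
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    for lab in labels:
        if len(epochs_by_label[lab]) < 2:
            raise ValueError(f"class {lab} has fewer than 2 epochs")
    if len(labels) == 2:
        a, b = labels
        return [
            fit_csp(
                epochs_by_label[a],
                epochs_by_label[b],
                n_components,
                class_pair=(a, b),
                band=band,
            )
        ]
    models = []
    for lab in labels:
        rest: list[np.ndarray] = []
        for other in labels:
            if other != lab:
                rest.extend(epochs_by_label[other])
        models.append(
            fit_csp(
                epochs_by_label[lab],
                rest,
                n_components,
                class_pair=(lab, "rest"),
                band=band,
            )
        )
    return models


def multiclass_features(models: Sequence[CSPModel], epoch: np.ndarray) -> np.ndarray:
    """Concatenated :func:`csp_features` across one-vs-rest models."""
    return np.concatenate([csp_features(m, epoch) for m in models])


def _encode_pair_element(c) -> str:
    if c is None:
        return "none:"
    if isinstance(c, (int, np.integer)):
        return f"int:{int(c)}"
    return f"str:{c}"


def _decode_pair_element(s: str):
    tag, _, val = s.partition(":")
    if tag == "none":
        return None
    if tag == "int":
        return int(val)
    return val


def save_model(model: CSPModel, path) -> None:
    """Serialize a model to a NumPy ``.npz`` container."""
    np.savez(
        path,
        filters=model.filters,
        eigenvalues=model.eigenvalues,
        n_components=model.n_components,
        class_pair=np.array([_encode_pair_element(c) for c in model.class_pair]),
        band=np.array(model.band or ""),
    )


def load_model(path) -> CSPModel:
    with np.load(path, allow_pickle=False) as data:
        band = str(data["band"])
        pair = tuple(_decode_pair_element(str(c)) for c in data["class_pair"])
        return CSPModel(
            filters=data["filters"],
            eigenvalues=data["eigenvalues"],
            n_components=int(data["n_components"]),
            class_pair=pair,
            band=band or None,
        )
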