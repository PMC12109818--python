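"""Readers/writers: session containers, feature tables and reports.

A "session" is a set of continuous recording segments with one emotion
label each (SEED-style sessions hold 15 segments).  Two on-disk forms
are supported: the package's portable NumPy container (``.npz`` with
named segment arrays, a label vector and the sampling rate) and MATLAB
v7 files as distributed with SEED (labels supplied separately via a
label map, since the files do not carry them).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
import scipy.io

from .pipeline import CVReport, FeatureTable

__all__ = [
    "SessionContainer",
    "write_session",
    "read_session",
    "write_features",
    "read_features",
    "write_report",
    "read_report",
    "config_hash",
]

EXPECTED_SEGMENTS = 15


@dataclass
class SessionContainer:
    """Continuous recording segments of one session."""

    segments: list[tuple[str, np.ndarray, int]]  # (name, channels x samples, label)
    fs: float
    subject: str | None = None
    session: str | None = None


def write_session(container: SessionContainer, path) -> None:
    arrays = {
        f"seg_{i:03d}_{name}": data
        for i, (name, data, _) in enumerate(container.segments)
    }
    np.savez(
        path,
        fs=container.fs,
        labels=np.array([lab for _, _, lab in container.segments], dtype=int),
        subject=np.array(container.subject or ""),
        session=np.array(container.session or ""),
        **arrays,
    )


def _read_npz(path: Path) -> SessionContainer:
    with np.load(path, allow_pickle=False) as data:
        fs = float(data["fs"])
        labels = data["labels"].astype(int)
        seg_keys = sorted(k for k in data.files if k.startswith("seg_"))
        if len(seg_keys) != len(labels):
            raise ValueError(
                f"{path}: {len(seg_keys)} segments but {len(labels)} labels"
            )
        segments = [
            (re.sub(r"^seg_\d{3}_", "", k), data[k], int(lab))
            for k, lab in zip(seg_keys, labels)
        ]
        subject = str(data["subject"]) or None
        session = str(data["session"]) or None
    return SessionContainer(segments=segments, fs=fs, subject=subject, session=session)


def _read_mat(path: Path, label_map: Sequence[int] | None, fs: float) -> SessionContainer:
    try:
        raw = scipy.io.loadmat(path)
    except Exception as err:
        raise ValueError(f"unreadable MATLAB file {path}: {err}") from err
    keys = [k for k in raw if not k.startswith("__") and isinstance(raw[k], np.ndarray)]

    def seg_index(key: str) -> int:
        m = re.search(r"(\d+)$", key)
        return int(m.group(1)) if m else 0

    keys.sort(key=seg_index)
    if label_map is None:
        raise ValueError(
            f"{path}: MATLAB sessions carry no labels; supply a label map "
            "(one label in {1, 0, -1} per segment, in stored order)"
        )
    if len(label_map) != len(keys):
        raise ValueError(
            f"{path}: {len(keys)} segments but {len(label_map)} labels in the map"
        )
    segments = [
        (k, np.asarray(raw[k], dtype=float), int(lab))
        for k, lab in zip(keys, label_map)
    ]
    return SessionContainer(segments=segments, fs=fs, subject=path.stem)


def read_session(
    path, label_map: Sequence[int] | None = None, fs: float = 200.0
) -> SessionContainer:
    """Load a session from ``.npz`` (self-describing) or ``.mat``.

    For MATLAB files the sampling rate defaults to 200 Hz and labels
    must be supplied via ``label_map``.  Warns when the segment count
    differs from the 15 expected for a SEED session.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such session file: {path}")
    if path.suffix == ".npz":
        container = _read_npz(path)
    else:
        container = _read_mat(path, label_map, fs)
    if len(container.segments) != EXPECTED_SEGMENTS:
        warnings.warn(
            f"{path}: expected {EXPECTED_SEGMENTS} segments, "
            f"found {len(container.segments)}",
            stacklevel=2,
        )
    bad = [lab for _, _, lab in container.segments if lab not in (1, 0, -1)]
    if bad:
        raise ValueError(f"{path}: labels must be in {{1, 0, -1}}, got {bad}")
    return container


def write_features(table: FeatureTable, path) -> None:
    """Feature table as CSV: epoch_id, band, f1..fN, label."""
    n_feat = table.X.shape[1]
    df = pd.DataFrame(table.X, columns=[f"f{i + 1}" for i in range(n_feat)])
    df.insert(0, "band", table.band)
    df.insert(0, "epoch_id", np.arange(len(df)))
    df["label"] = table.y
    df.attrs["window_k"] = table.window_k
    df.to_csv(path, index=False)


def read_features(path, window_k: int = 0) -> FeatureTable:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if re.fullmatch(r"f\d+", c)]
    return FeatureTable(
        X=df[feat_cols].to_numpy(float),
        y=df["label"].to_numpy(int),
        band=str(df["band"].iloc[0]) if len(df) else "",
        window_k=window_k,
    )


def config_hash(config) -> str:
    """Deterministic SHA-256 of a (dataclass) configuration."""
    payload = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report(report: CVReport, path, config=None) -> None:
    payload = {
        "task": list(report.task),
        "band": report.band,
        "window_k": report.window_k,
        "clf": report.clf,
        "mode": report.mode,
        "seed": report.seed,
        "fold_accuracies": report.fold_accuracies,
        "mean": report.mean,
        "std": report.std,
    }
    if config is not None:
        payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
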