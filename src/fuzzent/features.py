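"""Per-trial feature extraction and classifier-ready matrices.

Each (trial, channel) series yields a fused vector

    [FE, TSMFE_1 .. TSMFE_kmax, HMFE_A_L, HMFE_D_L, ..., HMFE_D_1]

— 16 values under the defaults (m=2, n=2, r = 0.15 sd, k_max=10,
db4 wavelet at level 4).  Multi-channel feature matrices concatenate
the per-channel blocks in the requested channel order.

Features are z-scored with statistics fit on the training fold only
(distance-based classifiers are scale-sensitive); the raw matrices are
kept available for classifiers that do not need it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fuzzent.fuzzy import FuzzyEntropyConfig, fuzzy_entropy
from fuzzent.hmfe import WaveletConfig, band_labels, hmfe
from fuzzent.io import TrialSet
from fuzzent.tsmfe import TimeShiftConfig, tsmfe

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "extract_trial_features",
    "build_feature_matrix",
    "standardize_train_apply",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Bundle of all entropy-estimator parameters."""

    fe: FuzzyEntropyConfig = field(default_factory=FuzzyEntropyConfig)
    k_max: int = 10
    wavelet: str = "db4"
    level: int = 4

    @property
    def n_features_per_channel(self) -> int:
        return 1 + self.k_max + self.level + 1

    def feature_names(self, channel: str) -> list[str]:
        names = [f"{channel}.FE"]
        names += [f"{channel}.TSMFE.{k}" for k in range(1, self.k_max + 1)]
        names += [f"{channel}.HMFE.{b}" for b in band_labels(self.level)]
        return names


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-trial fused feature vectors with name and channel provenance."""

    X: np.ndarray  # (n_trials, n_features)
    y: np.ndarray  # binary labels
    feature_names: tuple[str, ...]
    channels_used: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "channels_used", tuple(self.channels_used))
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must equal the number of rows of X")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must equal the number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(X).all():
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"non-finite feature value at trial {bad[0]}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "label", self.y)
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(
        cls, path: str | Path, channels_used: tuple[str, ...] = (), subject_id: str = ""
    ) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"feature CSV {path} has no 'label' column")
        y = df.pop("label").to_numpy(dtype=int)
        if not channels_used:
            channels_used = tuple(dict.fromkeys(c.split(".")[0] for c in df.columns))
        return cls(df.to_numpy(dtype=float), y, tuple(df.columns), channels_used, subject_id)


def extract_trial_features(
    trial_channel: np.ndarray, cfg: FeatureConfig | None = None
) -> np.ndarray:
    """Fused entropy features of one single-channel trial.

    Order: FE first, then the TSMFE scale vector, then the HMFE bands
    (approximation first, details coarse to fine).
    """
    if cfg is None:
        cfg = FeatureConfig()
    x = np.asarray(trial_channel, dtype=float)
    fe = fuzzy_entropy(x, cfg.fe).fe
    ts = tsmfe(x, TimeShiftConfig(k_max=cfg.k_max, base=cfg.fe)).values
    hm = hmfe(x, WaveletConfig(wavelet=cfg.wavelet, level=cfg.level, base=cfg.fe)).values
    return np.concatenate(([fe], ts, hm))


def build_feature_matrix(
    ts: TrialSet,
    channels: tuple[str, ...] | list[str] | None = None,
    cfg: FeatureConfig | None = None,
) -> FeatureMatrix:
    """Feature matrix over a channel subset: one row per trial.

    Per-channel feature blocks are concatenated in the requested order,
    so a two-channel request yields ``2 * (1 + k_max + level + 1)``
    columns.
    """
    if cfg is None:
        cfg = FeatureConfig()
    if channels is None:
        channels = ts.channels
    channels = tuple(channels)
    unknown = [c for c in channels if c not in ts.channels]
    if unknown:
        raise KeyError(f"unknown channel(s) {unknown}; available: {ts.channels}")

    blocks = []
    names: list[str] = []
    for ch in channels:
        series = ts.channel(ch)
        block = np.vstack([extract_trial_features(series[t], cfg) for t in range(ts.n_trials)])
        blocks.append(block)
        names += cfg.feature_names(ch)
    X = np.hstack(blocks)
    return FeatureMatrix(X, ts.labels, tuple(names), channels, ts.subject_id)


def standardize_train_apply(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Z-score features with mean/sd fit on the training rows only.

    Zero-variance training features map to 0 in both splits (with a
    warning) rather than dividing by zero.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s) mapped to 0",
            stacklevel=2,
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    Z_train = (X_train - mean) / safe_sd
    Z_test = (X_test - mean) / safe_sd
    Z_train[:, degenerate] = 0.0
    Z_test[:, degenerate] = 0.0
    return Z_train, Z_test, {"mean": mean, "sd": sd, "degenerate": degenerate}
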