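"""Signal containers, file I/O, preprocessing and epoching.

Continuous multi-channel recordings live in :class:`Recording`
(samples x channels, microvolts); epoched data in :class:`TrialSet`
(trial x channel x sample with binary labels, lie = 1 / truth = 0).

Conventions: sample indices are 0-based; epoch windows are half-open
``[t * w, (t + 1) * w)`` with ``w = round(trial_seconds * fs)``.

Preprocessing mirrors standard consumer-EEG practice: DC-offset removal
followed by a 0.5–45 Hz zero-phase band-pass, which strips slow drifts
and power-line interference while keeping the delta–beta rhythms.
Datasets whose manifest marks them as already preprocessed skip both
steps.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "TrialSet",
    "read_recording",
    "write_recording",
    "remove_dc",
    "bandpass_filter",
    "epoch_trials",
    "load_manifest",
    "save_manifest",
    "load_dataset",
]

#: Reference montage of the five-channel consumer headset.
MONTAGE = ("AF3", "T7", "PZ", "T8", "AF4")

LIE, TRUTH = 1, 0


@dataclass(frozen=True)
class Recording:
    """Continuous multi-channel signal with acquisition metadata."""

    data: np.ndarray  # (n_samples, n_channels), microvolts
    fs: float
    channels: tuple[str, ...]
    subject_id: str = ""
    condition: str = "unlabeled"  # {"lie", "truth", "unlabeled"}

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channels", tuple(self.channels))
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError(f"data must be a non-empty 2-D array, got {data.shape}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if len(self.channels) != data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {data.shape[1]} columns"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channel labels: {self.channels}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class TrialSet:
    """Epoched trials: array (n_trials, n_channels, n_samples_per_trial)."""

    trials: np.ndarray
    labels: np.ndarray  # binary, lie = 1 / truth = 0
    fs: float
    channels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        trials = np.asarray(self.trials, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "trials", trials)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channels", tuple(self.channels))
        if trials.ndim != 3:
            raise ValueError(f"trials must be 3-D, got shape {trials.shape}")
        if labels.shape != (trials.shape[0],):
            raise ValueError(
                f"{labels.shape[0] if labels.ndim else 0} labels for "
                f"{trials.shape[0]} trials"
            )
        if not np.isin(labels, (LIE, TRUTH)).all():
            raise ValueError("labels must be binary (lie = 1, truth = 0)")
        if len(self.channels) != trials.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {trials.shape[1]} channels"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def channel(self, label: str) -> np.ndarray:
        """All trials of one channel, shape (n_trials, n_samples)."""
        if label not in self.channels:
            raise KeyError(f"unknown channel {label!r}; available: {self.channels}")
        return self.trials[:, self.channels.index(label), :]


def read_recording(
    path: str | Path,
    fs: float,
    channels: tuple[str, ...] | list[str] | None = None,
    subject_id: str = "",
    condition: str = "unlabeled",
) -> Recording:
    """Read a continuous recording from CSV (or EDF via ``mne``).

    CSV layout: one sample per row, one channel per column, optional
    header row of channel labels.  When ``channels`` is given it must
    match the column count and overrides any header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    if path.suffix.lower() == ".edf":
        return _read_edf(path, channels, subject_id, condition)

    df = pd.read_csv(path, header=None)
    header_labels = None
    first_row = df.iloc[0]
    if first_row.map(lambda v: isinstance(v, str)).any():
        header_labels = tuple(str(v).strip() for v in first_row)
        df = df.iloc[1:].reset_index(drop=True)

    bad = df.map(lambda v: not _is_number(v))
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        offset = 2 if header_labels is not None else 1
        raise ValueError(
            f"non-numeric cell in {path} at row {rows[0] + offset}, "
            f"column {cols[0] + 1}: {df.iat[rows[0], cols[0]]!r}"
        )
    data = df.to_numpy(dtype=float)

    if channels is not None:
        channels = tuple(channels)
        if len(channels) != data.shape[1]:
            raise ValueError(
                f"channel list has {len(channels)} labels but {path} has "
                f"{data.shape[1]} columns"
            )
    elif header_labels is not None:
        channels = header_labels
    else:
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return Recording(data, fs, channels, subject_id, condition)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _read_edf(path, channels, subject_id, condition) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw = raw.pick(list(channels))
        labels = tuple(channels)
    else:
        labels = tuple(raw.ch_names)
    return Recording(raw.get_data().T * 1e6, raw.info["sfreq"], labels, subject_id, condition)


def write_recording(rec: Recording, path: str | Path, header: bool = True) -> None:
    """Write a recording as CSV, one sample per row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.data, columns=list(rec.channels))
    df.to_csv(path, index=False, header=header, float_format="%.10g")


def remove_dc(rec: Recording) -> Recording:
    """Subtract each channel's mean (DC offset removal)."""
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def bandpass_filter(
    rec: Recording, lo: float = 0.5, hi: float = 45.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass applied forward-backward.

    The two-pass (filtfilt) realization cancels group delay, so epoch
    boundaries are not shifted by the filter.
    """
    nyq = rec.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"high edge {hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=0)
    return replace(rec, data=np.ascontiguousarray(filtered))


def epoch_trials(
    rec: Recording,
    trial_seconds: float,
    labels: np.ndarray | list[int],
    trial_crop: tuple[float, float] | None = None,
) -> TrialSet:
    """Cut the recording into consecutive non-overlapping trials.

    Trial ``t`` covers samples ``[t * w, (t + 1) * w)`` with
    ``w = round(trial_seconds * fs)``.  A trailing remainder shorter
    than one trial is discarded with a warning.  ``trial_crop`` keeps
    only the ``[start, stop)`` second range inside each trial (e.g.
    ``(1.0, 3.0)`` to drop a 1-s prompt before a 2-s stimulus).

    Raises
    ------
    ValueError
        If the recording cannot supply as many trials as labels given.
    """
    labels = np.asarray(labels, dtype=int)
    w = int(round(trial_seconds * rec.fs))
    if w < 1:
        raise ValueError(f"trial window of {trial_seconds}s at fs={rec.fs} is empty")
    n_avail = rec.n_samples // w
    if n_avail < labels.shape[0]:
        raise ValueError(
            f"recording supplies {rec.n_samples} samples = {n_avail} trials of "
            f"{w} samples, but {labels.shape[0]} labels were given"
        )
    n_trials = labels.shape[0]
    remainder = rec.n_samples - n_trials * w
    if remainder > 0:
        logger.warning(
            "discarding %d trailing samples (%.2f s) after %d trials",
            remainder,
            remainder / rec.fs,
            n_trials,
        )
    trials = rec.data[: n_trials * w].reshape(n_trials, w, rec.n_channels)
    trials = np.transpose(trials, (0, 2, 1))
    if trial_crop is not None:
        start, stop = trial_crop
        i0, i1 = int(round(start * rec.fs)), int(round(stop * rec.fs))
        if not 0 <= i0 < i1 <= w:
            raise ValueError(f"trial_crop {trial_crop} outside the {w}-sample window")
        trials = trials[:, :, i0:i1]
    return TrialSet(trials, labels, rec.fs, rec.channels, rec.subject_id)


def save_manifest(manifest: dict, path: str | Path) -> None:
    """Write a dataset manifest (JSON)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_dataset(manifest_path: str | Path) -> dict[str, TrialSet]:
    """Load and epoch a manifest-described dataset into per-subject TrialSets.

    Each subject's per-condition continuous recordings are read,
    optionally preprocessed (DC removal + 0.5-45 Hz band-pass, skipped
    when the manifest marks the data as preprocessed), epoched into
    ``trial_seconds`` windows, and merged into one balanced TrialSet
    with the lie block first.
    """
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    root = manifest_path.parent
    fs = float(manifest["fs"])
    channels = tuple(manifest["channels"])
    trial_seconds = float(manifest.get("trial_seconds", 3.0))
    n_trials = int(manifest["n_trials_per_condition"])
    preprocessed = bool(manifest.get("preprocessed", False))

    dataset: dict[str, TrialSet] = {}
    for subject_id, files in manifest["subjects"].items():
        blocks, label_blocks = [], []
        for cond, label in (("lie", LIE), ("truth", TRUTH)):
            rec = read_recording(
                root / files[cond], fs, channels, subject_id, cond
            )
            if not preprocessed:
                rec = bandpass_filter(remove_dc(rec))
            ts = epoch_trials(rec, trial_seconds, np.full(n_trials, label))
            blocks.append(ts.trials)
            label_blocks.append(ts.labels)
        dataset[subject_id] = TrialSet(
            np.concatenate(blocks),
            np.concatenate(label_blocks),
            fs,
            channels,
            subject_id,
        )
    return dataset


def load_manifest(path: str | Path) -> dict:
    """Read a dataset manifest written by :func:`save_manifest`.

    Expected keys: ``fs``, ``channels``, ``preprocessed`` (bool) and
    ``subjects`` — a mapping subject id -> {condition -> csv path,
    relative to the manifest}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    manifest = json.loads(path.read_text())
    for key in ("fs", "channels", "subjects"):
        if key not in manifest:
            raise ValueError(f"manifest {path} missing required key {key!r}")
    return manifest
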