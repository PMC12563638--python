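"""Published reference results for the LieWaves lie-detection benchmark.

The CSVs packaged under ``fuzzent/data`` transcribe the per-subject
accuracies and representative-channel assignments reported for the
27-subject LieWaves study (five-channel consumer headset, 25 lie +
25 truth trials per subject).  They serve two purposes:

* validating the report-aggregation and channel-occurrence code against
  known published aggregates (e.g. the 82.74% within-subject LOOCV mean
  for LDA and the 64.07% cross-subject mean for the RBF SVM);
* providing realistic report fixtures without requiring the raw EEG
  download.

Classifier codes C1..C6 follow :mod:`fuzzent.evaluate`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "subject_dependent_accuracy",
    "cross_subject_accuracy",
    "best_channel_subject_dependent",
    "best_channel_cross_subject",
    "paired_channel_accuracy",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("fuzzent.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def subject_dependent_accuracy() -> pd.DataFrame:
    """Per-subject accuracies (%) for C1..C6 under within-subject CV.

    Long format: one row per (subject, scheme) with scheme in
    {"loocv", "kfold10"}.
    """
    return _load("subject_dependent_accuracy.csv")


def cross_subject_accuracy() -> pd.DataFrame:
    """Per-subject accuracies (%) for C1..C6 under leave-one-subject-out."""
    return _load("cross_subject_accuracy.csv")


def best_channel_subject_dependent() -> pd.DataFrame:
    """Representative channel and its accuracy per subject (LDA, within-subject)."""
    return _load("best_channel_subject_dependent.csv")


def best_channel_cross_subject() -> pd.DataFrame:
    """Representative channel and its accuracy per subject (RBF SVM, LOSOCV)."""
    return _load("best_channel_cross_subject.csv")


def paired_channel_accuracy() -> pd.DataFrame:
    """Two-channel (T7-PZ, T7-T8, PZ-T8) accuracies per subject.

    Wide format, columns ``<scheme>.<classifier>.<pair>`` for the two
    best classifiers (C2 = RBF SVM, C6 = LDA).
    """
    return _load("paired_channel_accuracy.csv")
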