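"""Time-shifted multi-scale fuzzy entropy (TSMFE).

Classic multi-scale entropy coarse-grains the series (averaging blocks
of k samples) before computing entropy at scale k, which smooths away
fine structure as the scale grows.  The time-shifted construction keeps
every original sample instead: at scale ``k`` the series is split into
``k`` interleaved subsequences — subsequence ``j`` starts at sample
``j`` and takes every ``k``-th sample — whose index sets partition the
series.  Fuzzy entropy is computed on each subsequence (tolerance
resolved on the subsequence itself by default) and the scale-k value is
the mean over the k subsequences.  Subsequences too short for the
embedding contribute 0, so deep scales on short trials remain defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fuzzent.fuzzy import (
    EntropyComputation,
    FuzzyEntropyConfig,
    ShortSeriesError,
    fuzzy_entropy,
)

__all__ = ["TimeShiftConfig", "TSMFEVector", "time_shift_subsequences", "tsmfe"]


@dataclass(frozen=True)
class TimeShiftConfig:
    """Parameters of the time-shifted multi-scale estimator.

    Parameters
    ----------
    k_max : int
        Largest time-shift scale; the output vector has one entry per
        scale ``1 .. k_max``.
    base : FuzzyEntropyConfig
        Fuzzy-entropy parameters applied to every subsequence.
    tolerance_on : {"subsequence", "series"}
        Whether the relative tolerance ``r_coef * sd`` is resolved on
        each subsequence (default) or once on the whole series.
    """

    k_max: int = 10
    base: FuzzyEntropyConfig = field(default_factory=FuzzyEntropyConfig)
    tolerance_on: str = "subsequence"

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError(f"k_max must be >= 1, got {self.k_max}")
        if self.tolerance_on not in ("subsequence", "series"):
            raise ValueError(
                f"tolerance_on must be 'subsequence' or 'series', got {self.tolerance_on!r}"
            )


@dataclass(frozen=True)
class TSMFEVector:
    """TSMFE feature vector plus per-subsequence detail.

    ``values[k-1]`` is the mean of the k per-subsequence fuzzy-entropy
    values at scale k (zero-fallbacks included in the mean).
    """

    values: np.ndarray
    per_scale_subseq_fe: tuple[tuple[float, ...], ...]
    degeneracy_flags: tuple[tuple[bool, ...], ...]


def time_shift_subsequences(x: np.ndarray, k: int) -> list[np.ndarray]:
    """Split ``x`` into ``k`` interleaved subsequences with step ``k``.

    Subsequence ``j`` (1-based) is ``(x_j, x_{j+k}, x_{j+2k}, ...)`` and
    has length ``floor((N - j) / k) + 1``.  The index sets of the k
    subsequences are pairwise disjoint and together cover the series.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"scale k={k} outside valid range [1, {n}]")
    return [x[j::k] for j in range(k)]


def tsmfe(x: np.ndarray, cfg: TimeShiftConfig | None = None) -> TSMFEVector:
    """Time-shifted multi-scale fuzzy entropy vector of length ``k_max``.

    At each scale k, any subsequence shorter than ``m + 2`` (or
    degenerate) contributes 0 to the scale mean rather than being
    dropped, keeping every scale an average over exactly k terms.

    Raises
    ------
    ShortSeriesError
        If the full series itself is shorter than ``m + 2``.
    """
    if cfg is None:
        cfg = TimeShiftConfig()
    x = np.asarray(x, dtype=float)
    min_len = cfg.base.m + 2
    if x.shape[0] < min_len:
        raise ShortSeriesError(
            f"series of length {x.shape[0]} too short for m={cfg.base.m}"
        )

    fe_cfg = cfg.base
    if cfg.tolerance_on == "series" and fe_cfg.r_abs is None:
        sd = float(np.std(x))
        fe_cfg = FuzzyEntropyConfig(
            m=fe_cfg.m,
            n=fe_cfg.n,
            r_coef=fe_cfg.r_coef,
            r_abs=fe_cfg.r_coef * sd if sd > 0 else None,
            baseline_removal=fe_cfg.baseline_removal,
        )

    values = np.empty(cfg.k_max, dtype=float)
    per_scale: list[tuple[float, ...]] = []
    flags: list[tuple[bool, ...]] = []
    for k in range(1, cfg.k_max + 1):
        subseqs = time_shift_subsequences(x, min(k, x.shape[0]))
        fes: list[float] = []
        degs: list[bool] = []
        for sub in subseqs:
            if sub.shape[0] < min_len:
                fes.append(0.0)
                degs.append(True)
                continue
            res = fuzzy_entropy(sub, fe_cfg)
            fes.append(res.fe if np.isfinite(res.fe) else 0.0)
            degs.append(res.degenerate or not np.isfinite(res.fe))
        # pad with zero-fallbacks if k exceeded the series length
        while len(fes) < k:
            fes.append(0.0)
            degs.append(True)
        values[k - 1] = float(np.mean(fes))
        per_scale.append(tuple(fes))
        flags.append(tuple(degs))
    return TSMFEVector(
        values=values,
        per_scale_subseq_fe=tuple(per_scale),
        degeneracy_flags=tuple(flags),
    )
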