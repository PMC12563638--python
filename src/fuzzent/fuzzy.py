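"""Fuzzy entropy of a univariate series.

Fuzzy entropy (FE) quantifies the irregularity of a time series by
comparing how often short patterns of length ``m`` remain similar when
extended to length ``m + 1``.  Similarity between pattern vectors is
graded with a smooth exponential membership function of their Chebyshev
distance, ``exp(-d**n / r)``, instead of the hard threshold used by
sample entropy, which makes the estimate continuous in the tolerance
``r`` and robust to small perturbations.

The estimator:

1. embed the series into overlapping ``m``-dimensional vectors
   ``X_i = (x_i, ..., x_{i+m-1})``, ``i = 1 .. N - m + 1``;
2. for every ordered pair ``i != j`` compute the Chebyshev distance
   ``d_ij = max_k |x_{i+k} - x_{j+k}|`` and the membership
   ``mu(d_ij) = exp(-d_ij**n / r)``;
3. average the memberships (excluding self pairs) to get the pattern
   matching degree ``phi_m``; repeat at dimension ``m + 1``;
4. ``FE = ln(phi_m) - ln(phi_{m+1})``.

Higher values mean patterns lose similarity faster when the embedding
grows, i.e. a more complex, less predictable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

__all__ = [
    "FuzzyEntropyConfig",
    "EntropyComputation",
    "ShortSeriesError",
    "embed_vectors",
    "chebyshev_distance",
    "membership",
    "phi",
    "fuzzy_entropy",
]

#: A series shorter than m + 2 cannot supply two vectors at dimension m + 1.
_MIN_EXTRA = 2

#: Standard-deviation floor below which a series is treated as constant.
DEGENERATE_SD = 1e-12


class ShortSeriesError(ValueError):
    """Raised when a series is too short for the requested embedding."""


@dataclass(frozen=True)
class FuzzyEntropyConfig:
    """Parameters of the fuzzy-entropy estimator.

    Parameters
    ----------
    m : int
        Embedding dimension — the length of the sliding pattern vectors.
    n : float
        Fuzzy factor, the exponent shaping the membership decay.
    r_coef : float
        Relative tolerance: the effective tolerance is ``r_coef`` times
        the standard deviation of the series being measured.
    r_abs : float, optional
        Absolute tolerance override.  When set it takes precedence over
        ``r_coef`` (used by the multi-band estimator, which rescales the
        tolerance per frequency band).
    baseline_removal : bool
        If True, subtract each pattern vector's own mean before
        measuring distances (a variant found in part of the fuzzy
        entropy literature).  Off by default: pattern vectors are the
        raw signal windows.
    """

    m: int = 2
    n: float = 2.0
    r_coef: float = 0.15
    r_abs: float | None = None
    baseline_removal: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.n <= 0:
            raise ValueError(f"fuzzy factor n must be > 0, got {self.n}")
        if self.r_abs is not None:
            if self.r_abs <= 0:
                raise ValueError(f"absolute tolerance must be > 0, got {self.r_abs}")
        elif self.r_coef <= 0:
            raise ValueError(f"tolerance coefficient must be > 0, got {self.r_coef}")


@dataclass(frozen=True)
class EntropyComputation:
    """Result of one fuzzy-entropy evaluation.

    ``fe = ln(phi_m) - ln(phi_m1)``; ``degenerate`` marks a constant
    (or tolerance-less) series for which the estimate is defined as 0.
    """

    fe: float
    phi_m: float = np.nan
    phi_m1: float = np.nan
    n_vectors_m: int = 0
    r: float = np.nan
    degenerate: bool = False


def embed_vectors(x: np.ndarray, m: int) -> np.ndarray:
    """Return the ``N - m + 1`` overlapping m-dimensional pattern vectors.

    Raises
    ------
    ShortSeriesError
        If ``len(x) < m + 2`` so that the matching degree at dimension
        ``m + 1`` could not be formed from at least two vectors.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    n = x.shape[0]
    if n < m + _MIN_EXTRA:
        raise ShortSeriesError(
            f"series of length {n} too short for embedding dimension {m} "
            f"(need at least {m + _MIN_EXTRA} samples)"
        )
    return sliding_window_view(x, m)


def chebyshev_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Maximum absolute coordinate-wise difference between two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))


def membership(d: float | np.ndarray, r: float, n: float) -> float | np.ndarray:
    """Exponential fuzzy membership ``exp(-d**n / r)`` in (0, 1]."""
    if r <= 0:
        raise ValueError(f"tolerance r must be > 0, got {r}")
    return np.exp(-np.power(d, n) / r)


def _membership_inplace(d: np.ndarray, r: float, n: float) -> np.ndarray:
    """exp(-d**n / r) without the generic-power cost for integer n."""
    if n == 2.0:
        mu = d * d
    elif n == 1.0:
        mu = d.copy()
    else:
        mu = np.power(d, n)
    mu /= -r
    np.exp(mu, out=mu)
    return mu


def _phi_from_distances(d: np.ndarray, r: float, n: float) -> float:
    """Pattern matching degree from a square distance matrix."""
    mu = _membership_inplace(d, r, n)
    count = d.shape[0]
    # mu[i, i] == 1 exactly; drop the self pair from each row.
    row_means = (mu.sum(axis=1) - 1.0) / (count - 1)
    return float(row_means.mean())


def _mean_membership(vectors: np.ndarray, r: float, n: float) -> float:
    """Average membership over all ordered pairs i != j of pattern vectors."""
    d = cdist(vectors, vectors, metric="chebyshev")
    return _phi_from_distances(d, r, n)


def _phi_pair(x: np.ndarray, m: int, r: float, n: float) -> tuple[float, float]:
    """Matching degrees at dimensions m and m + 1 from one shared
    sample-distance matrix.

    The Chebyshev distance between windows is the running maximum of
    ``|x_i - x_j|`` along the window offset, so both embedding depths
    share the same O(N^2) absolute-difference matrix.
    """
    a = np.abs(x[:, None] - x[None, :])
    v_m = x.shape[0] - m + 1
    d = a[:v_m, :v_m].copy()
    for off in range(1, m):
        np.maximum(d, a[off : off + v_m, off : off + v_m], out=d)
    v_m1 = v_m - 1
    d_m1 = np.maximum(d[:v_m1, :v_m1], a[m : m + v_m1, m : m + v_m1])
    return (
        _phi_from_distances(d, r, n),
        _phi_from_distances(d_m1, r, n),
    )


def phi(x: np.ndarray, m: int, r: float, n: float) -> float:
    """Pattern matching degree at dimension ``m``.

    The double average of pairwise memberships: outer mean over the
    ``N - m + 1`` pattern vectors, inner mean over the other ``N - m``.
    """
    vectors = embed_vectors(x, m)
    return _mean_membership(np.ascontiguousarray(vectors), r, n)


def _resolve_tolerance(x: np.ndarray, cfg: FuzzyEntropyConfig) -> float | None:
    """Effective tolerance for ``x``, or None when the series is degenerate."""
    if cfg.r_abs is not None:
        return cfg.r_abs
    sd = float(np.std(x))
    if sd < DEGENERATE_SD:
        return None
    return cfg.r_coef * sd


def fuzzy_entropy(
    x: np.ndarray, cfg: FuzzyEntropyConfig | None = None
) -> EntropyComputation:
    """Fuzzy entropy of a univariate series.

    The tolerance is resolved against the same series being measured
    (``r = r_coef * sd(x)``) unless an absolute override is configured.
    A constant series (sd below ``DEGENERATE_SD``) with no absolute
    tolerance yields ``fe = 0`` with the ``degenerate`` flag set, so
    that downstream averaging is not distorted.

    Raises
    ------
    ShortSeriesError
        If ``len(x) < m + 2``.
    """
    if cfg is None:
        cfg = FuzzyEntropyConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    if x.shape[0] < cfg.m + _MIN_EXTRA:
        raise ShortSeriesError(
            f"series of length {x.shape[0]} too short for m={cfg.m} "
            f"(need at least {cfg.m + _MIN_EXTRA} samples)"
        )
    r = _resolve_tolerance(x, cfg)
    if r is None:
        return EntropyComputation(fe=0.0, degenerate=True)

    if cfg.baseline_removal:
        vecs_m = embed_vectors(x, cfg.m)
        vecs_m1 = embed_vectors(x, cfg.m + 1)
        vecs_m = vecs_m - vecs_m.mean(axis=1, keepdims=True)
        vecs_m1 = vecs_m1 - vecs_m1.mean(axis=1, keepdims=True)
        phi_m = _mean_membership(np.ascontiguousarray(vecs_m), r, cfg.n)
        phi_m1 = _mean_membership(np.ascontiguousarray(vecs_m1), r, cfg.n)
    else:
        phi_m, phi_m1 = _phi_pair(x, cfg.m, r, cfg.n)
    if phi_m <= 0.0 or phi_m1 <= 0.0:
        # every pair membership underflowed: no similarity is resolvable
        # at this tolerance, so the log-ratio is undefined
        return EntropyComputation(
            fe=0.0,
            phi_m=phi_m,
            phi_m1=phi_m1,
            n_vectors_m=x.shape[0] - cfg.m + 1,
            r=r,
            degenerate=True,
        )
    fe = float(np.log(phi_m) - np.log(phi_m1))
    if abs(fe) < 1e-14:
        fe = 0.0
    return EntropyComputation(
        fe=fe,
        phi_m=phi_m,
        phi_m1=phi_m1,
        n_vectors_m=x.shape[0] - cfg.m + 1,
        r=r,
    )
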