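"""Independent brute-force reference implementations used as test oracles.

Everything here is written as straight-line enumeration of the estimator
definitions, deliberately independent of the optimized code paths in the
package: plain Python loops, no shared distance machinery.
"""

from __future__ import annotations

import math

import numpy as np
import pywt


def naive_phi(x, m, r, n):
    """Pattern matching degree by triple loop over vector pairs."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    V = N - m + 1
    vectors = [x[i : i + m] for i in range(V)]
    outer = 0.0
    for i in range(V):
        inner = 0.0
        for j in range(V):
            if j == i:
                continue
            d = max(abs(vectors[i][k] - vectors[j][k]) for k in range(m))
            inner += math.exp(-(d**n) / r)
        outer += inner / (V - 1)
    return outer / V


def naive_fuzzy_entropy(x, m=2, n=2.0, r_coef=0.15, r_abs=None):
    """FE = ln(phi_m) - ln(phi_{m+1}) by direct enumeration."""
    x = np.asarray(x, dtype=float)
    r = r_abs if r_abs is not None else r_coef * float(np.std(x))
    if r <= 0:
        return 0.0
    return math.log(naive_phi(x, m, r, n)) - math.log(naive_phi(x, m + 1, r, n))


def naive_tsmfe(x, k_max=10, m=2, n=2.0, r_coef=0.15):
    """Scale vector by direct subsequence enumeration with zero-fallback."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    out = []
    for k in range(1, k_max + 1):
        fes = []
        for j in range(1, k + 1):
            sub = np.array([x[i] for i in range(j - 1, N, k)])
            if len(sub) < m + 2 or float(np.std(sub)) < 1e-12:
                fes.append(0.0)
            else:
                fes.append(naive_fuzzy_entropy(sub, m=m, n=n, r_coef=r_coef))
        out.append(sum(fes) / k)
    return np.array(out)


def naive_hmfe(x, wavelet="db4", level=4, m=2, n=2.0, r_coef=0.15):
    """Per-band FE by explicit zero-out-and-invert reconstruction."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    sigma_x = float(np.std(x))
    r = r_coef * sigma_x
    values = []
    for b in range(level + 1):
        kept = [c if i == b else np.zeros_like(c) for i, c in enumerate(coeffs)]
        band = pywt.waverec(kept, wavelet, mode="periodization")[:N]
        sigma_b = float(np.std(band))
        if sigma_x < 1e-12 or sigma_b / sigma_x < 1e-8:
            values.append(0.0)
        else:
            values.append(naive_fuzzy_entropy(band, m=m, n=n, r_abs=r * sigma_b / sigma_x))
    return np.array(values)
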