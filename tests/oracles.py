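"""Naive reference implementations used as independent oracles.

Everything here is written for clarity, not speed: plain double loops and
textbook formulas, kept deliberately separate from the package's
optimised code paths.
"""

from __future__ import annotations

import math

import numpy as np


def naive_moments(x) -> tuple[float, float, float, float]:
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    if sd == 0:
        return mean, 0.0, 0.0, 0.0
    kur = (sum((v - mean) ** 4 for v in x) / n) / var**2
    sk = (sum((v - mean) ** 3 for v in x) / n) / var**1.5
    return mean, sd, kur, sk


def _chebyshev(a, b) -> float:
    return max(abs(u - v) for u, v in zip(a, b))


def naive_sample_entropy(x, m: int, r: float) -> float:
    """-log(A/B) over all template pairs i<j of the first N-m templates."""
    x = list(map(float, x))
    nt = len(x) - m
    B = 0
    A = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if _chebyshev(x[i : i + m], x[j : j + m]) <= r:
                B += 1
            if _chebyshev(x[i : i + m + 1], x[j : j + m + 1]) <= r:
                A += 1
    if A == 0 or B == 0:
        return -math.log(2.0 / ((len(x) - m - 1) * (len(x) - m)))
    return -math.log(A / B)


def naive_sample_entropy_counts(x, m: int, r: float) -> tuple[int, int]:
    x = list(map(float, x))
    nt = len(x) - m
    B = sum(
        1
        for i in range(nt - 1)
        for j in range(i + 1, nt)
        if _chebyshev(x[i : i + m], x[j : j + m]) <= r
    )
    A = sum(
        1
        for i in range(nt - 1)
        for j in range(i + 1, nt)
        if _chebyshev(x[i : i + m + 1], x[j : j + m + 1]) <= r
    )
    return B, A


def naive_fuzzy_entropy(x, m: int, r: float, n_exp: float = 2.0) -> float:
    """-log(phi_{m+1}/phi_m) with membership exp(-(d/r)^n) over pairs."""
    x = list(map(float, x))
    nt = len(x) - m
    phi_m = 0.0
    phi_m1 = 0.0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = _chebyshev(x[i : i + m], x[j : j + m])
            d1 = _chebyshev(x[i : i + m + 1], x[j : j + m + 1])
            phi_m += math.exp(-((d / r) ** n_exp))
            phi_m1 += math.exp(-((d1 / r) ** n_exp))
    return -math.log(phi_m1 / phi_m)


def naive_permutation_entropy(x, order: int, delay: int) -> float:
    """Base-2 Shannon entropy of ordinal patterns; ties broken by index."""
    x = list(map(float, x))
    n_vec = len(x) - (order - 1) * delay
    counts: dict[tuple, int] = {}
    for i in range(n_vec):
        vec = [x[i + k * delay] for k in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: (vec[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def naive_confusion(y_true, y_pred) -> dict:
    tally = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tally["TP"] += 1
        elif t == 0 and p == 1:
            tally["FP"] += 1
        elif t == 0 and p == 0:
            tally["TN"] += 1
        else:
            tally["FN"] += 1
    return tally


def naive_band_power_fraction(x, fs: int, lo: float, hi: float,
                              total_lo: float, total_hi: float) -> float:
    """Fraction of periodogram power in [lo, hi) relative to [total_lo, total_hi)."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    band = spec[(freqs >= lo) & (freqs < hi)].sum()
    total = spec[(freqs >= total_lo) & (freqs < total_hi)].sum()
    return float(band / total)
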