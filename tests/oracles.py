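"""Independent brute-force oracles used only by the tests.

These deliberately use naive O(L·W log W) / O(N²) formulations so they
share no code path with the package implementations they check.
"""
from __future__ import annotations

import numpy as np


def naive_running_median(x, size: int) -> np.ndarray:
    """Centered running median via explicit sorting, symmetric padding."""
    assert size % 2 == 1
    x = np.asarray(x, dtype=float)
    half = size // 2
    padded = np.pad(x, half, mode="symmetric")
    out = np.empty(x.size)
    for i in range(x.size):
        window = np.sort(padded[i:i + size])
        out[i] = window[half]
    return out


def coarse_traditional_oracle(x, tau: int) -> list[float]:
    """Non-overlapping block means by explicit loop; tail discarded."""
    out = []
    i = 0
    while i + tau <= len(x):
        out.append(sum(x[i:i + tau]) / tau)
        i += tau
    return out


def coarse_improved_oracle(x, tau: int) -> list[float]:
    """Sliding windows of length tau advanced by round-half-up(tau/2)."""
    step = max(1, int(np.floor(tau / 2 + 0.5)))
    out = []
    i = 0
    while i + tau <= len(x):
        out.append(sum(x[i:i + tau]) / tau)
        i += step
    return out


def sampen_bruteforce(y, m: int, r: float) -> float:
    """Sample entropy by explicit pairwise template comparison.

    Uses N−m templates at both lengths m and m+1 (the standard
    convention), Chebyshev distance, self-matches excluded.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    n_templates = n - m

    def pair_count(length: int) -> float:
        templates = np.array([y[i:i + length] for i in range(n_templates)])
        total = 0
        for i in range(n_templates):
            d = np.max(np.abs(templates - templates[i]), axis=1)
            total += int(np.sum(d <= r)) - 1  # exclude the self-match
        return total / 2.0

    b = pair_count(m)
    a = pair_count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))
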