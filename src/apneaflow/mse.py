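"""Multiscale sample entropy with traditional and sliding-window coarse-graining.

Sample entropy (SampEn) is the negative log conditional probability that
two subsequences matching for ``m`` points within tolerance ``r`` (in
Chebyshev distance, self-matches excluded) still match at ``m+1``
points.  Multiscale entropy evaluates SampEn on coarse-grained copies of
the series at scale factors τ = 1..15.

Traditional coarse-graining averages non-overlapping blocks of length τ,
discarding up to τ−1 tail samples.  The sliding-window variant instead
averages windows of length τ advanced by 50 % of the window (step
``round(τ/2)``, ties up), which keeps the tail whenever it completes a
window and roughly doubles the coarse-series length — reducing the
variance of the entropy estimate at large scales.

The pair counting is done with a k-d tree under the Chebyshev metric;
an O(N²) brute-force oracle lives in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SampEnParams:
    """Entropy parameters: embedding dimension ``m``, tolerance ``r``
    (as a fraction of the source-series standard deviation), and the
    largest scale factor."""

    m: int = 2
    r: float = 0.2
    scale_max: int = 15

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not 0.0 < self.r < 1.0:
            raise ValueError("tolerance fraction r must lie in (0, 1)")
        if self.scale_max < 1:
            raise ValueError("scale_max must be >= 1")


@dataclass
class CoarseSeries:
    """A coarse-grained series at one scale factor."""

    values: np.ndarray
    scale: int
    source_length: int
    method: str


def improved_step(scale: int) -> int:
    """Sliding-window advance: 50 % of the window, ties rounded up."""
    return max(1, (scale + 1) // 2)


def coarse_grain_traditional(x, scale: int) -> CoarseSeries:
    """Non-overlapping block means; the L mod τ tail is discarded."""
    x = np.asarray(x, dtype=float)
    L = x.size
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale > L:
        raise ValueError(f"scale {scale} exceeds series length {L}")
    if scale == 1:
        vals = x.copy()
    else:
        nb = L // scale
        vals = x[:nb * scale].reshape(nb, scale).mean(axis=1)
    return CoarseSeries(vals, scale, L, "traditional")


def coarse_grain_improved(x, scale: int) -> CoarseSeries:
    """Sliding-window means of length τ advanced by ``improved_step(τ)``."""
    x = np.asarray(x, dtype=float)
    L = x.size
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if scale > L:
        raise ValueError(f"scale {scale} exceeds series length {L}")
    if scale == 1:
        return CoarseSeries(x.copy(), scale, L, "improved")
    step = improved_step(scale)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    starts = np.arange(0, L - scale + 1, step)
    vals = (csum[starts + scale] - csum[starts]) / scale
    return CoarseSeries(vals, scale, L, "improved")


def _pair_count(y: np.ndarray, length: int, n_templates: int,
                r: float) -> int:
    """Unordered template pairs (i<j, among the first ``n_templates``
    templates of the given length) with Chebyshev distance <= r."""
    if n_templates < 2:
        return 0
    emb = np.lib.stride_tricks.sliding_window_view(y, length)[:n_templates]
    tree = cKDTree(np.ascontiguousarray(emb))
    total = tree.count_neighbors(tree, r, p=np.inf)
    return int((total - n_templates) // 2)


def sample_entropy(y, params: SampEnParams | None = None,
                   r_abs: float | None = None) -> float:
    """SampEn(m, r) of a series.

    Template counts follow the standard convention (N−m templates at both
    lengths m and m+1), so a constant series yields exactly 0.  The
    tolerance is ``r_abs`` if given, else ``params.r`` times the SD of
    ``y``.  Returns NaN when no template pair matches at either length
    (the estimate is undefined); downstream feature assembly imputes and
    masks such entries.
    """
    params = params or SampEnParams()
    y = np.asarray(y, dtype=float)
    m = params.m
    if y.size < m + 2:
        raise ValueError(f"series of length {y.size} too short for m={m}")
    if r_abs is None:
        r_abs = params.r * float(y.std())
    n_templates = y.size - m
    b = _pair_count(y, m, n_templates, r_abs)
    a = _pair_count(y, m + 1, n_templates, r_abs)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


@dataclass
class ScaleEntropyVector:
    """SampEn at scale factors 1..scale_max for one analysis window."""

    scales: np.ndarray
    values: np.ndarray
    params: SampEnParams
    method: str

    @property
    def undefined(self) -> np.ndarray:
        """Mask of scales where the entropy estimate is undefined."""
        return ~np.isfinite(self.values)

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(v) for s, v in zip(self.scales, self.values)}


def mse_vector(x, params: SampEnParams | None = None,
               method: str = "improved") -> ScaleEntropyVector:
    """Multiscale entropy curve MSE(τ), τ = 1..scale_max.

    The tolerance r is referenced to the SD of the *original* series (the
    common multiscale convention), so entries at different scales share
    one absolute tolerance.  Scales whose coarse series is too short, or
    where no templates match, yield NaN entries flagged via
    :attr:`ScaleEntropyVector.undefined`.
    """
    params = params or SampEnParams()
    x = np.asarray(x, dtype=float)
    if method not in ("traditional", "improved"):
        raise ValueError("method must be 'traditional' or 'improved'")
    coarsen = (coarse_grain_traditional if method == "traditional"
               else coarse_grain_improved)
    r_abs = params.r * float(x.std())
    scales = np.arange(1, params.scale_max + 1)
    values = np.full(scales.size, np.nan)
    for i, tau in enumerate(scales):
        if tau > x.size:
            continue
        y = coarsen(x, int(tau)).values
        if y.size < params.m + 2:
            continue
        values[i] = sample_entropy(y, params, r_abs=r_abs)
    return ScaleEntropyVector(scales, values, params, method)
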