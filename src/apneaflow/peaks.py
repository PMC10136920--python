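"""Pulse-peak detection by dyadic wavelet modulus-maxima pairing.

The record is decomposed with the quadratic-spline (Mallat–Zhong) dyadic
wavelet, implemented as an undecimated à-trous FIR cascade, at scale
s = 2³.  This wavelet behaves as a smoothed derivative, so the rising
edge of each pulse produces a positive modulus maximum, the falling edge
a negative one, and the zero-crossing between the pair localizes the
waveform peak.  Candidate pairs must exceed adaptive thresholds
(thp > 0 > thn), have a monotone coefficient path between them (an
extremum without a matching partner is an orphan and is dropped), and
accepted peaks suppress further candidates for a 200-ms refractory
period.  Gaps longer than 1.5× the mean peak-to-peak interval are
re-scanned at 4/5 of the thresholds to recover missed beats; the
thresholds are restored afterwards.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import PPGRecord

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.2
RECOVERY_GAP_FACTOR = 1.5
RECOVERY_THRESHOLD_FACTOR = 0.8  # the 4/5 reduced-threshold rule

# Quadratic-spline filter bank: smoothing h and derivative-like g.
_H = np.array([0.125, 0.375, 0.375, 0.125])
_G = np.array([2.0, -2.0])


def _upsample(f: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return f
    out = np.zeros((f.size - 1) * k + 1)
    out[::k] = f
    return out


def _atrous_kernel(level: int = 3) -> np.ndarray:
    """Equivalent FIR kernel of the level-``level`` à-trous detail branch."""
    k = _H.copy()
    for j in range(1, level - 1):
        k = np.convolve(k, _upsample(_H, 2 ** j))
    return np.convolve(k, _upsample(_G, 2 ** (level - 1)))


def _kernel_center(k: np.ndarray) -> int:
    # The detail kernel is anti-symmetric about its center c, so the
    # autoconvolution (k*k) attains its minimum at index 2c.
    return int(round(np.argmin(np.convolve(k, k)) / 2))


@dataclass
class WaveletDecomposition:
    """Undecimated detail coefficients W_{2^3} f(n), aligned to the input."""

    coefficients: np.ndarray
    scale: int
    alignment: int
    sampling_rate_hz: float


@dataclass(frozen=True)
class ThresholdPair:
    """Positive/negative modulus-maxima acceptance thresholds."""

    thp: float
    thn: float

    def __post_init__(self):
        if not (self.thp > 0 > self.thn):
            raise ValueError("require thp > 0 > thn")

    def reduced(self, factor: float = RECOVERY_THRESHOLD_FACTOR):
        return ThresholdPair(self.thp * factor, self.thn * factor)


@dataclass
class PeakTrain:
    """Detected pulse peaks: strictly increasing sample indices plus the
    signal amplitude at each peak."""

    peak_indices: np.ndarray
    peak_amplitudes: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self):
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_indices.size != self.peak_amplitudes.size:
            raise ValueError("indices and amplitudes must align")
        if self.peak_indices.size > 1 and np.any(
                np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.peak_indices / self.sampling_rate_hz

    @property
    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.peak_indices) / self.sampling_rate_hz * 1000.0


def wavelet_scale3(rec: PPGRecord) -> WaveletDecomposition:
    """Detail coefficients at scale 2³, same length as the input.

    Alignment is corrected so the + → − zero-crossing of a pulse's
    maxima pair falls on the pulse peak sample.
    """
    kernel = _atrous_kernel(3)
    if rec.n_samples < 2 * kernel.size:
        raise ValueError(
            f"record too short for scale-8 analysis: {rec.n_samples} samples")
    c = _kernel_center(kernel)
    # edge padding keeps boundary coefficients zero for constant inputs
    # (the detail kernel sums to zero) and avoids spurious edge maxima
    pad = kernel.size
    padded = np.pad(rec.samples, pad, mode="edge")
    full = np.convolve(padded, kernel)
    coeff = full[c + pad:c + pad + rec.n_samples]
    return WaveletDecomposition(coeff, 8, c, rec.sampling_rate_hz)


def _local_extrema(w: np.ndarray):
    interior = w[1:-1]
    maxima = np.nonzero((interior >= w[:-2]) & (interior > w[2:]))[0] + 1
    minima = np.nonzero((interior <= w[:-2]) & (interior < w[2:]))[0] + 1
    return maxima, minima


def _find_pairs_arr(w: np.ndarray, thp: np.ndarray, thn: np.ndarray,
                    mono_tol: float = 0.05) -> list[tuple[int, int]]:
    """Maxima-pair search against per-sample threshold arrays."""
    maxima, minima = _local_extrema(w)
    maxima = maxima[w[maxima] > thp[maxima]]
    minima = minima[w[minima] < thn[minima]]
    events = sorted([(int(i), +1) for i in maxima]
                    + [(int(i), -1) for i in minima])
    pairs = []
    i = 0
    while i < len(events) - 1:
        (p, sp), (q, sq) = events[i], events[i + 1]
        if sp == +1 and sq == -1:
            seg = w[p:q + 1]
            tol = mono_tol * (w[p] - w[q])
            if np.all(np.diff(seg) <= tol):
                pairs.append((p, q))
                i += 2
                continue
        i += 1  # orphan or non-monotone pair member: drop and move on
    return pairs


def find_maxima_pairs(dec: WaveletDecomposition, thr: ThresholdPair,
                      mono_tol: float = 0.05) -> list[tuple[int, int]]:
    """Positive/negative extremum pairs above threshold with a monotone
    coefficient path between them; orphan extrema are removed."""
    w = dec.coefficients
    thp = np.full(w.size, thr.thp)
    thn = np.full(w.size, thr.thn)
    return _find_pairs_arr(w, thp, thn, mono_tol)


def locate_peaks(pairs, dec: WaveletDecomposition) -> np.ndarray:
    """Peak candidates at the zero-crossing inside each maxima pair
    (linear interpolation, rounded to the nearest sample)."""
    w = dec.coefficients
    out = []
    for p, q in pairs:
        seg = w[p:q + 1]
        cross = np.nonzero((seg[:-1] >= 0) & (seg[1:] < 0))[0]
        if cross.size == 0:
            logger.warning("maxima pair (%d, %d) has no sign change; skipped",
                           p, q)
            continue
        k = p + int(cross[0])
        frac = w[k] / (w[k] - w[k + 1])
        out.append(int(round(k + frac)))
    return np.asarray(sorted(set(out)), dtype=int)


def apply_refractory(candidates, sampling_rate_hz: float,
                     amplitudes=None) -> PeakTrain:
    """Greedy left-to-right suppression of candidates closer than 200 ms
    to the previously accepted peak."""
    candidates = np.asarray(candidates, dtype=int)
    ref = int(round(REFRACTORY_S * sampling_rate_hz))
    kept = []
    for c in candidates:
        if not kept or c - kept[-1] >= ref:
            kept.append(int(c))
    kept = np.asarray(kept, dtype=int)
    if amplitudes is None:
        amps = np.full(kept.size, np.nan)
    else:
        amplitudes = np.asarray(amplitudes, dtype=float)
        amps = amplitudes[kept] if kept.size else np.empty(0)
    return PeakTrain(kept, amps, sampling_rate_hz)


def _recover_missed_arr(train: PeakTrain, dec: WaveletDecomposition,
                        thp: np.ndarray, thn: np.ndarray,
                        samples=None) -> PeakTrain:
    fs = train.sampling_rate_hz
    if train.n_peaks < 2:
        return train
    idx = train.peak_indices
    mean_pp = float(np.mean(np.diff(idx)))
    ref = int(round(REFRACTORY_S * fs))
    new_candidates = list(idx)
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a <= RECOVERY_GAP_FACTOR * mean_pp:
            continue
        lo, hi = a + ref, b - ref
        if hi - lo < 3:
            continue
        sub = dec.coefficients[lo:hi]
        pairs = _find_pairs_arr(sub,
                                thp[lo:hi] * RECOVERY_THRESHOLD_FACTOR,
                                thn[lo:hi] * RECOVERY_THRESHOLD_FACTOR)
        if not pairs:
            logger.warning("gap (%d, %d) exceeds %.1fx mean interval but no "
                           "sub-threshold pair found", a, b,
                           RECOVERY_GAP_FACTOR)
            continue
        subdec = WaveletDecomposition(sub, dec.scale, dec.alignment, fs)
        for c in locate_peaks(pairs, subdec):
            new_candidates.append(int(lo + c))
    new_candidates = sorted(set(new_candidates))
    return apply_refractory(new_candidates, fs, amplitudes=samples)


def recover_missed(train: PeakTrain, dec: WaveletDecomposition,
                   thr: ThresholdPair, samples=None) -> PeakTrain:
    """Re-detect inside gaps longer than 1.5× the mean peak-to-peak
    interval at 4/5 of the thresholds; refractory is re-enforced and the
    original thresholds apply afterwards (single pass over gaps)."""
    n = dec.coefficients.size
    thp = np.full(n, thr.thp)
    thn = np.full(n, thr.thn)
    return _recover_missed_arr(train, dec, thp, thn, samples=samples)


def adaptive_thresholds(w: np.ndarray, sampling_rate_hz: float,
                        c: float = 1.5, chunk_s: float = 60.0):
    """Per-sample threshold arrays: within each 60-s chunk,
    thp = c·RMS(positive coefficients) and thn = −c·RMS(negative ones).

    Chunks without coefficients of one sign get an infinite threshold
    (nothing can fire there).
    """
    n = w.size
    chunk = max(1, int(round(chunk_s * sampling_rate_hz)))
    thp = np.full(n, np.inf)
    thn = np.full(n, -np.inf)
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        seg = w[lo:hi]
        pos = seg[seg > 0]
        neg = seg[seg < 0]
        if pos.size:
            thp[lo:hi] = c * np.sqrt(np.mean(pos ** 2))
        if neg.size:
            thn[lo:hi] = -c * np.sqrt(np.mean(neg ** 2))
    return thp, thn


def detect_peaks(rec: PPGRecord, threshold_scale: float = 1.5,
                 mono_tol: float = 0.05) -> PeakTrain:
    """Full detection pipeline on a (preprocessed) PPG record.

    Thresholds adapt per 60-s chunk; the missed-beat recovery pass runs
    once over all long gaps with the chunk thresholds reduced to 4/5.
    """
    dec = wavelet_scale3(rec)
    w = dec.coefficients
    thp, thn = adaptive_thresholds(w, rec.sampling_rate_hz, c=threshold_scale)
    pairs = _find_pairs_arr(w, thp, thn, mono_tol)
    candidates = locate_peaks(pairs, dec)
    train = apply_refractory(candidates, rec.sampling_rate_hz,
                             amplitudes=rec.samples)
    if train.n_peaks >= 2:
        train = _recover_missed_arr(train, dec, thp, thn,
                                    samples=rec.samples)
    return train
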