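"""PPG preprocessing: baseline removal, median denoising, IIR lowpass.

The chain mirrors a conventional wearable front end: a long running
median (window 2.5·N samples, N the sampling rate) estimates baseline
wander, which is subtracted; a shorter running median rejects impulsive
noise; an IIR lowpass (Chebyshev type II — stopband-ripple family) with a
4.8 Hz cutoff suppresses EMG-band and power-line interference.  The
lowpass delay is compensated by dropping the first M/2 output samples,
M the filter order.  Finally the record is cut into 60-second analysis
windows slid by one second.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .records import PPGRecord, SignalWindow


def _odd_window(window_s: float, fs: float) -> int:
    w = int(round(window_s * fs))
    if w < 1:
        w = 1
    if w % 2 == 0:
        w += 1
    return w


def _running_median(x: np.ndarray, size: int) -> np.ndarray:
    # mode="reflect" in ndimage repeats the edge sample (symmetric padding),
    # matching np.pad(..., mode="symmetric") in the naive oracle.
    return ndimage.median_filter(x, size=size, mode="reflect")


def remove_baseline(rec: PPGRecord, window_s: float = 2.5) -> PPGRecord:
    """Subtract the running-median baseline estimate (window 2.5 s).

    The running median of a quasi-periodic pulse train tracks the slow
    wander while ignoring the beats; subtracting it leaves a zero-mean
    pulse signal.
    """
    size = _odd_window(window_s, rec.sampling_rate_hz)
    if rec.n_samples < size:
        raise ValueError(
            f"record too short for baseline removal: {rec.n_samples} samples "
            f"< window {size}")
    baseline = _running_median(rec.samples, size)
    return PPGRecord(rec.samples - baseline, rec.sampling_rate_hz)


def median_denoise(rec: PPGRecord, window_s: float = 2.0) -> PPGRecord:
    """Centered running median of window ``round(window_s * fs)``, odd-adjusted.

    Each output sample is the median of its centered neighborhood with
    reflect padding at the edges.
    """
    size = _odd_window(window_s, rec.sampling_rate_hz)
    if rec.n_samples < size:
        raise ValueError(
            f"record too short for median denoising: {rec.n_samples} samples "
            f"< window {size}")
    return PPGRecord(_running_median(rec.samples, size), rec.sampling_rate_hz)


@dataclass
class LowpassDesign:
    """An IIR lowpass design plus its verified frequency response.

    ``stopband_edge_hz`` is the lowest frequency at which the attenuation
    first reaches the stopband spec; beyond it the response stays at or
    below ``-stopband_atten_db``.
    """

    order: int
    cutoff_hz: float
    stopband_atten_db: float
    passband_ripple_db: float
    sampling_rate_hz: float
    sos: np.ndarray
    stopband_edge_hz: float

    def frequency_response(self, n_points: int = 4096):
        freqs, h = sps.sosfreqz(self.sos, worN=n_points,
                                fs=self.sampling_rate_hz)
        with np.errstate(divide="ignore"):
            gain_db = 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))
        return freqs, gain_db

    def group_delay_samples(self, freq_hz: float) -> float:
        """Group delay (samples) at ``freq_hz``, summed over sections."""
        total = 0.0
        for sec in self.sos:
            b, a = sec[:3], sec[3:]
            w, gd = sps.group_delay((b, a), w=[freq_hz],
                                    fs=self.sampling_rate_hz)
            total += float(gd[0])
        return total


class FilterDesignError(ValueError):
    """Raised when the requested lowpass spec is infeasible."""


def design_lowpass(
        sampling_rate_hz: float,
        order: int = 10,
        cutoff_hz: float = 4.8,
        stopband_atten_db: float = 60.0,
        passband_ripple_db: float = 1.0,
) -> LowpassDesign:
    """Design a Chebyshev-II lowpass meeting the requested attenuation specs.

    The stopband edge is found by bisection as the smallest frequency such
    that the passband deviation at ``cutoff_hz`` stays within
    ``passband_ripple_db``; the Chebyshev-II structure then guarantees at
    least ``stopband_atten_db`` of attenuation beyond the edge.  The
    returned design is verified against both specs on a dense grid and a
    :class:`FilterDesignError` is raised if either fails.
    """
    nyq = sampling_rate_hz / 2.0
    if order < 1:
        raise FilterDesignError("filter order must be a positive integer")
    if not 0 < cutoff_hz < nyq:
        raise FilterDesignError("cutoff must lie below the Nyquist frequency")

    def atten_at_cutoff(ws: float) -> float:
        sos = sps.cheby2(order, stopband_atten_db, ws, btype="low",
                         fs=sampling_rate_hz, output="sos")
        _, h = sps.sosfreqz(sos, worN=np.array([cutoff_hz]),
                            fs=sampling_rate_hz)
        return -20.0 * np.log10(max(abs(h[0]), 1e-300))

    lo, hi = cutoff_hz * 1.0001, nyq * 0.9999
    if atten_at_cutoff(hi) > passband_ripple_db:
        raise FilterDesignError(
            f"order-{order} Chebyshev II cannot meet {stopband_atten_db} dB "
            f"stopband with <= {passband_ripple_db} dB ripple at "
            f"{cutoff_hz} Hz (fs={sampling_rate_hz})")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if atten_at_cutoff(mid) > passband_ripple_db:
            lo = mid
        else:
            hi = mid
    ws = hi
    sos = sps.cheby2(order, stopband_atten_db, ws, btype="low",
                     fs=sampling_rate_hz, output="sos")

    design = LowpassDesign(order=order, cutoff_hz=cutoff_hz,
                           stopband_atten_db=stopband_atten_db,
                           passband_ripple_db=passband_ripple_db,
                           sampling_rate_hz=sampling_rate_hz, sos=sos,
                           stopband_edge_hz=ws)
    freqs, gain_db = design.frequency_response(8192)
    pb = freqs <= cutoff_hz
    sb = freqs >= ws
    tol = 1e-6
    if np.any(np.abs(gain_db[pb]) > passband_ripple_db + tol):
        raise FilterDesignError("passband ripple spec not met")
    if np.any(gain_db[sb] > -stopband_atten_db + tol):
        raise FilterDesignError("stopband attenuation spec not met")
    return design


def apply_lowpass(rec: PPGRecord, design: LowpassDesign) -> PPGRecord:
    """Filter and drop the first M/2 samples (delay compensation).

    Output length is ``len(input) - order // 2``.
    """
    if abs(design.sampling_rate_hz - rec.sampling_rate_hz) > 1e-9:
        raise ValueError(
            f"design was made for fs={design.sampling_rate_hz} Hz, record has "
            f"fs={rec.sampling_rate_hz} Hz")
    y = sps.sosfilt(design.sos, rec.samples)
    drop = design.order // 2
    return PPGRecord(y[drop:], rec.sampling_rate_hz)


def compute_snr(signal_power: float, noise_power: float) -> float:
    """Signal-to-noise ratio 10·log10(Ps/Pn) in dB."""
    if signal_power <= 0 or noise_power <= 0:
        raise ValueError("powers must be positive")
    return 10.0 * np.log10(signal_power / noise_power)


def segment_windows(
        rec: PPGRecord,
        labels=None,
        window_s: float = 60.0,
        step_s: float = 1.0,
) -> list[SignalWindow]:
    """Cut the record into ``window_s`` windows slid by ``step_s``.

    ``labels`` are optional per-minute apnea flags; a window takes the
    label of the minute containing at least half of it (ties go to the
    earlier minute).
    """
    fs = rec.sampling_rate_hz
    wlen = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    if rec.n_samples < wlen:
        raise ValueError(
            f"record ({rec.n_samples} samples) shorter than one "
            f"{window_s:g}-s window")
    if labels is not None:
        labels = np.asarray(labels, dtype=bool)

    windows = []
    for start in range(0, rec.n_samples - wlen + 1, step):
        start_s = start / fs
        label = None
        if labels is not None and labels.size:
            k0 = int(start_s // 60)
            k1 = int((start_s + window_s) // 60)
            best_k, best_ov = None, -1.0
            for k in range(k0, k1 + 1):
                ov = min(start_s + window_s, 60.0 * (k + 1)) - max(
                    start_s, 60.0 * k)
                if ov > best_ov + 1e-12:
                    best_ov = ov
                    best_k = k
            best_k = min(best_k, labels.size - 1)
            label = bool(labels[best_k])
        windows.append(SignalWindow(rec.samples[start:start + wlen],
                                    start_s, fs, label))
    return windows
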