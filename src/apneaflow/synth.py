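"""Synthetic PPG / SpO2 recordings with known ground truth.

The generator produces quasi-periodic pulse waves (a two-Gaussian
systolic/dicrotic template per beat) with controllable beat-to-beat
variability, plus the three interference classes seen in practice:
power-line pickup, high-frequency EMG-like noise, and low-frequency
baseline wander.  Apnea episodes modulate the beat-interval variability
and pulse amplitude so that apneic windows are statistically separable
from normal ones, and depress the companion SpO2 series below 90 %.
Probe-loosening intervals produce a *non-pathological* SpO2 drop with
collapsed AC amplitude, flagged in the ground truth.

Nothing here aims at hemodynamic realism — the point is a controllable
test bed with exact ground truth (beat times, minute labels, SpO2).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import PPGRecord

# Pulse template shape (seconds). The systolic lobe carries the peak; the
# smaller dicrotic lobe trails it by a fixed delay.
_SYSTOLIC_WIDTH_S = 0.08
_DICROTIC_DELAY_S = 0.30
_DICROTIC_WIDTH_S = 0.16
_DICROTIC_AMP_FRAC = 0.30
_AMP_JITTER_SD = 0.02

# SpO2 dynamics (percent / seconds).
_SPO2_BASELINE = 97.5
_SPO2_NADIR = 85.0
_SPO2_ART_FLOOR = 75.0
_DESAT_LAG_S = 2.0
_DESAT_FALL_TAU_S = 4.0
_DESAT_RECOVER_TAU_S = 10.0

# Dual-wavelength construction.
_AC_MODULATION = 0.03
_ARTIFACT_AC_FRAC = 0.05


def _validate_intervals(intervals, duration_s, name):
    out = []
    prev_end = -np.inf
    for iv in intervals:
        s, e = float(iv[0]), float(iv[1])
        if not (0.0 <= s < e <= duration_s):
            raise ValueError(f"{name} interval ({s}, {e}) outside [0, {duration_s}]")
        if s < prev_end:
            raise ValueError(f"{name} intervals must be sorted and non-overlapping")
        prev_end = e
        out.append((s, e))
    return tuple(out)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for one synthetic recording.

    ``hr_variability_sd_ms`` is the beat-interval standard deviation of
    normal sleep; inside apnea episodes it is multiplied by
    ``apnea_sd_factor`` and the pulse amplitude by ``apnea_amp_factor``.
    Noise amplitudes are in units of the (unit) pulse amplitude.
    """

    sampling_rate_hz: float = 100.0
    duration_s: float = 300.0
    base_heart_rate_bpm: float = 70.0
    hr_variability_sd_ms: float = 30.0
    apnea_episodes: tuple = ()
    apnea_sd_factor: float = 3.0
    apnea_amp_factor: float = 0.8
    noise_powerline_amp: float = 0.0
    powerline_freq_hz: float = 50.0
    noise_emg_amp: float = 0.0
    baseline_drift_amp: float = 0.0
    spo2_artifact_intervals: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not 40.0 <= self.base_heart_rate_bpm <= 180.0:
            raise ValueError("base_heart_rate_bpm must lie in [40, 180]")
        if self.hr_variability_sd_ms < 0:
            raise ValueError("hr_variability_sd_ms must be non-negative")
        for name in ("noise_powerline_amp", "noise_emg_amp", "baseline_drift_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        object.__setattr__(
            self, "apnea_episodes",
            _validate_intervals(self.apnea_episodes, self.duration_s, "apnea"))
        object.__setattr__(
            self, "spo2_artifact_intervals",
            _validate_intervals(self.spo2_artifact_intervals, self.duration_s,
                                "spo2_artifact"))


@dataclass
class GroundTruth:
    """Exact generative truth for one recording.

    ``window_labels`` carries one apnea flag per full minute (the label
    unit used for training); ``spo2_series`` / ``artifact_flags`` are per
    second and filled by :func:`generate_spo2`.  ``clean_pulse`` is the
    noise-free waveform, kept so the dual-wavelength channels can share
    the exact pulse shape.
    """

    peak_indices: np.ndarray
    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    window_labels: np.ndarray
    spo2_series: np.ndarray | None = None
    artifact_flags: np.ndarray | None = None
    clean_pulse: np.ndarray | None = None
    sampling_rate_hz: float = 100.0
    duration_s: float = 0.0


def _in_any(t: float, intervals) -> bool:
    return any(s <= t < e for s, e in intervals)


def generate_ppg(config: SynthConfig) -> tuple[PPGRecord, GroundTruth]:
    """Synthesize one PPG record and its ground truth.

    Deterministic for a fixed config (bit-identical output).  Beat times
    follow a Gaussian interval model N(60/HR, sd); within apnea episodes
    the interval sd is multiplied by ``apnea_sd_factor`` and the beat
    amplitude by ``apnea_amp_factor``.
    """
    cfg = config
    fs = cfg.sampling_rate_hz
    n = int(round(cfg.duration_s * fs))
    ss = np.random.SeedSequence(cfg.seed)
    r_beat, r_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    mean_pp = 60.0 / cfg.base_heart_rate_bpm
    sd_base = cfg.hr_variability_sd_ms / 1000.0

    beat_times, beat_amps = [], []
    t = mean_pp / 2.0
    while t < cfg.duration_s:
        apneic = _in_any(t, cfg.apnea_episodes)
        amp = cfg.apnea_amp_factor if apneic else 1.0
        amp *= 1.0 + _AMP_JITTER_SD * r_beat.standard_normal()
        beat_times.append(t)
        beat_amps.append(max(amp, 0.05))
        sd = sd_base * (cfg.apnea_sd_factor if apneic else 1.0)
        interval = float(np.clip(r_beat.normal(mean_pp, sd), 0.3, 2.0))
        t += interval
    beat_times = np.asarray(beat_times)
    beat_amps = np.asarray(beat_amps)

    tgrid = np.arange(n) / fs
    clean = np.zeros(n)
    half = 4.0 * (_DICROTIC_DELAY_S + _DICROTIC_WIDTH_S)
    for tb, a in zip(beat_times, beat_amps):
        lo = max(0, int((tb - half) * fs))
        hi = min(n, int((tb + half) * fs) + 1)
        tt = tgrid[lo:hi] - tb
        clean[lo:hi] += a * np.exp(-0.5 * (tt / _SYSTOLIC_WIDTH_S) ** 2)
        clean[lo:hi] += (a * _DICROTIC_AMP_FRAC
                         * np.exp(-0.5 * ((tt - _DICROTIC_DELAY_S)
                                          / _DICROTIC_WIDTH_S) ** 2))

    x = clean.copy()
    if cfg.noise_powerline_amp > 0:
        phase = r_noise.uniform(0, 2 * np.pi)
        x += cfg.noise_powerline_amp * np.sin(
            2 * np.pi * cfg.powerline_freq_hz * tgrid + phase)
    if cfg.noise_emg_amp > 0:
        white = r_noise.standard_normal(n)
        hp_hz = min(10.0, 0.45 * fs)
        sos = sps.butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
        emg = sps.sosfilt(sos, white)
        s = emg.std()
        if s > 0:
            x += cfg.noise_emg_amp * emg / s
    if cfg.baseline_drift_amp > 0:
        walk = np.cumsum(r_noise.standard_normal(n))
        sos = sps.butter(2, min(0.4, 0.45 * fs), btype="lowpass", fs=fs,
                         output="sos")
        drift = sps.sosfilt(sos, walk)
        drift -= drift.mean()
        s = drift.std()
        if s > 0:
            x += cfg.baseline_drift_amp * drift / s

    peak_idx = np.round(beat_times * fs).astype(int)
    keep = peak_idx < n
    n_min = int(cfg.duration_s // 60)
    labels = np.zeros(n_min, dtype=bool)
    for k in range(n_min):
        lo, hi = 60.0 * k, 60.0 * (k + 1)
        for s, e in cfg.apnea_episodes:
            if min(e, hi) - max(s, lo) > 1e-9:
                labels[k] = True
                break

    truth = GroundTruth(
        peak_indices=peak_idx[keep],
        peak_times_s=beat_times[keep],
        peak_amplitudes=beat_amps[keep],
        window_labels=labels,
        clean_pulse=clean,
        sampling_rate_hz=fs,
        duration_s=cfg.duration_s,
    )
    return PPGRecord(x, fs), truth


def generate_spo2(config: SynthConfig, truth: GroundTruth) -> GroundTruth:
    """Fill the per-second SpO2 series and artifact flags of ``truth``.

    Baseline saturation sits in [96, 99] %.  Each apnea episode produces a
    lagged exponential fall toward ~85 % followed by an exponential
    recovery; probe-loosening intervals produce a fast non-pathological
    drop toward 75 % with ``artifact_flags`` set.
    """
    cfg = config
    n_sec = int(np.floor(cfg.duration_s))
    if n_sec < 1:
        raise ValueError("duration too short for an SpO2 series")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    t = np.arange(n_sec, dtype=float)
    base = (_SPO2_BASELINE
            + 0.5 * np.sin(2 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi))
            + 0.1 * rng.standard_normal(n_sec))
    base = np.clip(base, 96.0, 99.0)

    dip = np.zeros(n_sec)
    for s, e in cfg.apnea_episodes:
        depth = base - _SPO2_NADIR
        t0 = s + _DESAT_LAG_S
        fall = np.where(
            (t >= t0) & (t < e),
            1.0 - np.exp(-np.maximum(t - t0, 0.0) / _DESAT_FALL_TAU_S), 0.0)
        d_end = max(0.0, 1.0 - np.exp(-(e - t0) / _DESAT_FALL_TAU_S))
        rec = np.where(
            t >= e,
            d_end * np.exp(-np.maximum(t - e, 0.0) / _DESAT_RECOVER_TAU_S),
            0.0)
        dip = np.maximum(dip, depth * np.maximum(fall, rec))

    flags = np.zeros(n_sec, dtype=bool)
    for s, e in cfg.spo2_artifact_intervals:
        depth = base - _SPO2_ART_FLOOR
        fall = np.where((t >= s) & (t < e),
                        1.0 - np.exp(-np.maximum(t - s, 0.0) / 1.0), 0.0)
        d_end = max(0.0, 1.0 - np.exp(-(e - s) / 1.0))
        rec = np.where(t >= e,
                       d_end * np.exp(-np.maximum(t - e, 0.0) / 2.0), 0.0)
        dip = np.maximum(dip, depth * np.maximum(fall, rec))
        flags |= (t >= s) & (t < e)

    spo2 = np.clip(base - dip, 0.0, 100.0)
    return dataclasses.replace(truth, spo2_series=spo2, artifact_flags=flags)


def generate_dual_wavelength(
        config: SynthConfig, truth: GroundTruth
) -> tuple[PPGRecord, PPGRecord]:
    """Construct red/IR intensity channels encoding ``truth.spo2_series``.

    Both channels share the clean pulse waveform; the red channel's AC/DC
    modulation is scaled by the ratio R = (110 - SpO2)/25 so that the
    package's own ratio-of-ratios calibration recovers the target series.
    During probe-loosening intervals the AC of both channels collapses to
    a small fraction so quality heuristics can flag those seconds.
    """
    if truth.spo2_series is None or truth.clean_pulse is None:
        raise ValueError("truth must carry spo2_series and clean_pulse "
                         "(run generate_ppg then generate_spo2 first)")
    fs = config.sampling_rate_hz
    n = truth.clean_pulse.size
    sec = np.minimum((np.arange(n) / fs).astype(int),
                     truth.spo2_series.size - 1)
    spo2 = truth.spo2_series[sec]
    ratio = (110.0 - spo2) / 25.0

    p = truth.clean_pulse - truth.clean_pulse.mean()
    ptp = np.ptp(p)
    if ptp > 0:
        p = p / ptp

    ac_frac = np.ones(n)
    tgrid = np.arange(n) / fs
    for s, e in config.spo2_artifact_intervals:
        ac_frac[(tgrid >= s) & (tgrid < e)] = _ARTIFACT_AC_FRAC

    ir = 1.0 + _AC_MODULATION * ac_frac * p
    red = 1.0 + _AC_MODULATION * ac_frac * ratio * p
    return PPGRecord(red, fs), PPGRecord(ir, fs)


def generate_recording(config: SynthConfig):
    """Convenience: full bundle (ppg, red, ir, truth with SpO2)."""
    rec, truth = generate_ppg(config)
    truth = generate_spo2(config, truth)
    red, ir = generate_dual_wavelength(config, truth)
    return rec, red, ir, truth


def make_training_corpus(
        seed: int,
        n_records: int = 16,
        minutes_per_record: int = 6,
        sampling_rate_hz: float = 100.0,
        minute_apnea_prob: float = 0.45,
        hr_variability_sd_ms: float = 30.0,
        noise_powerline_amp: float = 0.02,
        noise_emg_amp: float = 0.05,
        baseline_drift_amp: float = 0.3,
) -> list[SynthConfig]:
    """Configurations for a labelled synthetic training corpus.

    Each record is ``minutes_per_record`` long; each minute is apneic with
    probability ``minute_apnea_prob`` (adjacent apneic minutes merge into
    one episode).  The corpus is guaranteed to contain both classes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    configs: list[SynthConfig] = []
    any_pos = any_neg = False
    for k in range(n_records):
        flags = rng.random(minutes_per_record) < minute_apnea_prob
        if k == n_records - 1:
            if not any_pos:
                flags[:] = True
            if not any_neg:
                flags[:] = False
        episodes = []
        start = None
        for m, f in enumerate(list(flags) + [False]):
            if f and start is None:
                start = 60.0 * m
            elif not f and start is not None:
                episodes.append((start, 60.0 * m))
                start = None
        any_pos |= bool(flags.any())
        any_neg |= bool((~flags).any())
        configs.append(SynthConfig(
            sampling_rate_hz=sampling_rate_hz,
            duration_s=60.0 * minutes_per_record,
            base_heart_rate_bpm=float(rng.uniform(55.0, 80.0)),
            hr_variability_sd_ms=hr_variability_sd_ms,
            apnea_episodes=tuple(episodes),
            noise_powerline_amp=noise_powerline_amp,
            noise_emg_amp=noise_emg_amp,
            baseline_drift_amp=baseline_drift_amp,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return configs
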