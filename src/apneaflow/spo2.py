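"""Pulse oximetry: ratio-of-ratios SpO2, desaturation events, artifact gating.

Saturation is the oxygenated fraction of hemoglobin,
SpO2 = C_HbO2 / (C_HbO2 + C_Hb) × 100.  From dual-wavelength intensity
channels it is estimated per second through the ratio of normalized
pulsatile amplitudes R = (AC_red/DC_red) / (AC_ir/DC_ir) and the
conventional empirical calibration SpO2 = 110 − 25·R.

Runs of seconds below 90 % form desaturation events.  An event is
*non-pathological* (probe loosening, motion, weak perfusion) when at
least half of its seconds carry signal-quality flags — such events are
excluded from apnea confirmation and raise a user-visible warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import PPGRecord

logger = logging.getLogger(__name__)

DESAT_THRESHOLD_PCT = 90.0
ARTIFACT_OVERLAP_FRAC = 0.5

# Linear calibration SpO2 = CAL_A - CAL_B * R.
CAL_A = 110.0
CAL_B = 25.0


def spo2_fraction(c_hbo2: float, c_hb: float) -> float:
    """Saturation from hemoglobin concentrations (definition formula)."""
    total = c_hbo2 + c_hb
    if total <= 0:
        raise ValueError("total hemoglobin concentration must be positive")
    return c_hbo2 / total * 100.0


@dataclass
class OximetrySeries:
    """Per-second SpO2 values with per-second quality/artifact flags
    (True = suspect second)."""

    values: np.ndarray
    quality_flags: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.quality_flags = np.asarray(self.quality_flags, dtype=bool)
        if self.values.shape != self.quality_flags.shape:
            raise ValueError("values and flags must align")

    @property
    def n_seconds(self) -> int:
        return int(self.values.size)


@dataclass
class DesatEvent:
    """A maximal run of sub-threshold SpO2 seconds."""

    start_s: float
    end_s: float
    min_spo2: float
    pathological: bool = True


def compute_spo2(red: PPGRecord, ir: PPGRecord,
                 cal_a: float = CAL_A, cal_b: float = CAL_B) -> OximetrySeries:
    """Per-second ratio-of-ratios SpO2 from red/IR intensity channels.

    AC is the per-second peak-to-peak excursion, DC the per-second mean.
    Seconds with vanishing AC or non-positive DC on either channel are
    marked invalid (quality flag set, value NaN).
    """
    if red.n_samples != ir.n_samples:
        raise ValueError("red and IR channels must have equal length")
    if abs(red.sampling_rate_hz - ir.sampling_rate_hz) > 1e-9:
        raise ValueError("red and IR channels must share a sampling rate")
    fs = red.sampling_rate_hz
    n_sec = int(red.n_samples // fs)
    if n_sec < 1:
        raise ValueError("need at least one full second of data")
    values = np.full(n_sec, np.nan)
    flags = np.ones(n_sec, dtype=bool)
    spp = int(round(fs))
    for s in range(n_sec):
        r = red.samples[s * spp:(s + 1) * spp]
        i = ir.samples[s * spp:(s + 1) * spp]
        dc_r, dc_i = r.mean(), i.mean()
        ac_r, ac_i = np.ptp(r), np.ptp(i)
        if dc_r <= 0 or dc_i <= 0 or ac_r <= 0 or ac_i <= 0:
            continue
        ratio = (ac_r / dc_r) / (ac_i / dc_i)
        values[s] = float(np.clip(cal_a - cal_b * ratio, 0.0, 100.0))
        flags[s] = False
    return OximetrySeries(values, flags)


def ppg_quality_flags(rec: PPGRecord, floor_frac: float = 0.1) -> np.ndarray:
    """Per-second signal-quality flags from pulsatile-amplitude proxies.

    A second is suspect when its peak-to-peak excursion falls below
    ``floor_frac`` of the record's median per-second excursion (probe
    loosening / weak perfusion), is exactly zero (dropout), or is
    non-finite.
    """
    fs = rec.sampling_rate_hz
    n_sec = int(rec.n_samples // fs)
    spp = int(round(fs))
    ptps = np.array([np.ptp(rec.samples[s * spp:(s + 1) * spp])
                     for s in range(n_sec)])
    med = np.median(ptps[ptps > 0]) if np.any(ptps > 0) else 0.0
    return (~np.isfinite(ptps)) | (ptps <= 0) | (ptps < floor_frac * med)


def detect_desaturation(series: OximetrySeries,
                        threshold_pct: float = DESAT_THRESHOLD_PCT
                        ) -> list[DesatEvent]:
    """Maximal runs of seconds with SpO2 below the threshold."""
    below = np.nan_to_num(series.values, nan=np.inf) < threshold_pct
    events = []
    start = None
    for s, flag in enumerate(np.append(below, False)):
        if flag and start is None:
            start = s
        elif not flag and start is not None:
            seg = series.values[start:s]
            events.append(DesatEvent(float(start), float(s),
                                     float(np.nanmin(seg))))
            start = None
    return events


def classify_artifact(event: DesatEvent, series: OximetrySeries,
                      ppg_quality=None) -> DesatEvent:
    """Decide whether a desaturation is pathological.

    The event is attributed to a signal artifact (non-pathological) when
    at least half of its seconds carry a quality flag, combining the
    oximetry flags with optional per-second PPG quality flags.
    """
    lo, hi = int(event.start_s), int(event.end_s)
    flags = series.quality_flags[lo:hi].copy()
    if ppg_quality is not None:
        q = np.asarray(ppg_quality, dtype=bool)[lo:hi]
        flags[:q.size] |= q
    frac = flags.mean() if flags.size else 0.0
    pathological = frac < ARTIFACT_OVERLAP_FRAC
    if not pathological:
        logger.warning(
            "SpO2 drop at %.0f-%.0f s (min %.1f%%) attributed to signal "
            "artifact; check sensor contact", event.start_s, event.end_s,
            event.min_spo2)
    return DesatEvent(event.start_s, event.end_s, event.min_spo2,
                      pathological)
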