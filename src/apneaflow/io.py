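"""File I/O: CSV recordings (mandatory) and optional WFDB/EDF readers.

Recording CSV layout: columns ``time_s, ppg`` with optional ``red``,
``ir`` and ``spo2`` columns.  The sampling rate is inferred from the
time column unless given.  Ground-truth CSVs are written as separate
peak / minute-label / artifact tables.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import PPGRecord
from .synth import GroundTruth


def write_recording_csv(path, rec: PPGRecord, red: PPGRecord | None = None,
                        ir: PPGRecord | None = None,
                        spo2_per_second=None) -> None:
    data = {"time_s": rec.times_s, "ppg": rec.samples}
    if red is not None:
        data["red"] = red.samples
    if ir is not None:
        data["ir"] = ir.samples
    if spo2_per_second is not None:
        sec = np.minimum(np.floor(rec.times_s).astype(int),
                         len(spo2_per_second) - 1)
        data["spo2"] = np.asarray(spo2_per_second, dtype=float)[sec]
    pd.DataFrame(data).to_csv(path, index=False)


def read_recording_csv(path, sampling_rate_hz: float | None = None):
    """Read a recording CSV; returns (ppg, red, ir, spo2_per_second).

    Channels absent from the file come back as None.
    """
    df = pd.read_csv(path)
    if "ppg" not in df.columns:
        raise ValueError(f"{path}: no 'ppg' column")
    if sampling_rate_hz is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise ValueError(
                f"{path}: need a time_s column (or explicit rate) to infer "
                f"the sampling rate")
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        sampling_rate_hz = round(1.0 / dt, 6)
    ppg = PPGRecord(df["ppg"].to_numpy(), sampling_rate_hz)
    red = PPGRecord(df["red"].to_numpy(), sampling_rate_hz) \
        if "red" in df.columns else None
    ir = PPGRecord(df["ir"].to_numpy(), sampling_rate_hz) \
        if "ir" in df.columns else None
    spo2 = None
    if "spo2" in df.columns:
        sec = np.floor(df["time_s"].to_numpy()).astype(int) \
            if "time_s" in df.columns else \
            (np.arange(len(df)) / sampling_rate_hz).astype(int)
        n_sec = int(sec.max()) + 1
        spo2 = np.full(n_sec, np.nan)
        spo2[sec] = df["spo2"].to_numpy()
    return ppg, red, ir, spo2


def write_truth_csv(prefix, truth: GroundTruth) -> None:
    """Write ground truth as <prefix>_peaks.csv / _labels.csv / _spo2.csv."""
    prefix = Path(prefix)
    pd.DataFrame({"peak_index": truth.peak_indices,
                  "peak_time_s": truth.peak_times_s,
                  "peak_amplitude": truth.peak_amplitudes}).to_csv(
        f"{prefix}_peaks.csv", index=False)
    pd.DataFrame({"window_index": np.arange(truth.window_labels.size),
                  "label": truth.window_labels.astype(int)}).to_csv(
        f"{prefix}_labels.csv", index=False)
    if truth.spo2_series is not None:
        pd.DataFrame({"second": np.arange(truth.spo2_series.size),
                      "spo2": truth.spo2_series,
                      "artifact": truth.artifact_flags.astype(int)}).to_csv(
            f"{prefix}_spo2.csv", index=False)


def write_peaks_csv(path, train) -> None:
    pd.DataFrame({"sample_index": train.peak_indices,
                  "time_s": train.times_s,
                  "amplitude": train.peak_amplitudes}).to_csv(path,
                                                              index=False)


def read_wfdb(record_path, channel: str | int = 0) -> PPGRecord:
    """Read one channel of a WFDB record (requires the ``wfdb`` package,
    not installed by default)."""
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install wfdb)") from exc
    rec = wfdb.rdrecord(str(record_path))
    if isinstance(channel, str):
        channel = list(rec.sig_name).index(channel)
    return PPGRecord(rec.p_signal[:, channel], float(rec.fs))


def read_edf(path, channel: str | int = 0) -> PPGRecord:
    """Read one channel of an EDF export (requires ``pyedflib``,
    not installed by default)."""
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF files requires the optional 'pyedflib' package "
            "(pip install pyedflib)") from exc
    with pyedflib.EdfReader(str(path)) as f:
        if isinstance(channel, str):
            channel = list(f.getSignalLabels()).index(channel)
        x = f.readSignal(channel)
        fs = f.getSampleFrequency(channel)
    return PPGRecord(x, float(fs))
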