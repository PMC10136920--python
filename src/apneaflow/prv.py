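"""Pulse-rate-variability features and combined feature assembly.

Nine time-domain statistics per 60-s window, computed from the detected
peak train: pulse rate, mean / SD / median of the peak-to-peak (PP)
intervals, NN50 and pNN50 (successive-difference counts at the 50-ms
boundary), and mean / SD / median of the peak amplitudes.  Dispersion
statistics use the sample SD (ddof=1), the HRV convention.  pNN50 is
reported as a fraction in [0, 1]; multiply by 100 for a percentage.

Windows with fewer than three peaks cannot support dispersion
statistics; they yield NaN entries that feature assembly imputes with
the column median (mask recorded), so no information silently leaks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mse import ScaleEntropyVector
from .peaks import PeakTrain

NN50_THRESHOLD_MS = 50.0

PRV_COLUMNS = ("pr", "pp_mean_ms", "sdnn_pp_ms", "pp_median_ms",
               "nn50", "pnn50", "sdnn_aa", "aa_mean", "aa_median")


@dataclass
class PRVFeatureSet:
    """Time-domain variability statistics of one window's peak train."""

    pr: float                # pulse beats per minute
    pp_mean_ms: float
    sdnn_pp_ms: float
    pp_median_ms: float
    nn50: float
    pnn50: float             # fraction of successive differences > 50 ms
    sdnn_aa: float
    aa_mean: float
    aa_median: float
    degenerate: bool = False

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in PRV_COLUMNS], dtype=float)


def compute_prv(train: PeakTrain, window_duration_s: float) -> PRVFeatureSet:
    """PRV features of a peak train over a window of known duration.

    With fewer than three peaks, only the rate is computable; the rest
    are NaN and the set is flagged degenerate.
    """
    if window_duration_s <= 0:
        raise ValueError("window duration must be positive")
    n = train.n_peaks
    pr = n * 60.0 / window_duration_s
    if n < 3:
        return PRVFeatureSet(pr, *([np.nan] * 8), degenerate=True)
    pp = train.intervals_ms
    dd = np.diff(pp)
    nn50 = int(np.sum(np.abs(dd) > NN50_THRESHOLD_MS))
    pnn50 = nn50 / dd.size if dd.size else np.nan
    amps = train.peak_amplitudes
    amps_ok = np.all(np.isfinite(amps))
    return PRVFeatureSet(
        pr=pr,
        pp_mean_ms=float(pp.mean()),
        sdnn_pp_ms=float(pp.std(ddof=1)),
        pp_median_ms=float(np.median(pp)),
        nn50=float(nn50),
        pnn50=float(pnn50),
        sdnn_aa=float(amps.std(ddof=1)) if amps_ok else np.nan,
        aa_mean=float(amps.mean()) if amps_ok else np.nan,
        aa_median=float(np.median(amps)) if amps_ok else np.nan,
    )


@dataclass
class FeatureMatrix:
    """Assembled per-window features: entropy scales then PRV columns.

    ``values`` is imputed (column medians; 0.0 where a column is entirely
    undefined); ``mask`` marks imputed cells; ``raw`` keeps the NaNs.
    """

    values: np.ndarray
    mask: np.ndarray
    raw: np.ndarray
    columns: list[str]
    labels: np.ndarray | None = None
    medians: np.ndarray | None = None


def impute_columns(raw: np.ndarray, medians: np.ndarray | None = None):
    """Replace NaNs with per-column medians (training medians if given)."""
    values = raw.copy()
    mask = ~np.isfinite(raw)
    if medians is None:
        medians = np.zeros(raw.shape[1]) if raw.size == 0 else np.array([
            np.nanmedian(col) if np.any(np.isfinite(col)) else 0.0
            for col in raw.T])
        medians = np.where(np.isfinite(medians), medians, 0.0)
    rows, cols = np.nonzero(mask)
    values[rows, cols] = medians[cols]
    return values, mask, medians


def assemble_features(entropy_vectors: list[ScaleEntropyVector],
                      prv_sets: list[PRVFeatureSet],
                      labels=None,
                      medians: np.ndarray | None = None) -> FeatureMatrix:
    """Stack entropy + PRV vectors into a (n_windows × (scale_max + 9))
    matrix with a fixed, documented column order."""
    if len(entropy_vectors) != len(prv_sets):
        raise ValueError("entropy and PRV lists must align")
    if labels is not None and len(labels) != len(prv_sets):
        raise ValueError("labels must align with windows")
    if not entropy_vectors:
        cols = [f"mse_s{s}" for s in range(1, 16)] + list(PRV_COLUMNS)
        empty = np.empty((0, len(cols)))
        return FeatureMatrix(empty, empty.astype(bool), empty.copy(), cols,
                             None, medians)
    scale_max = int(entropy_vectors[0].scales[-1])
    cols = [f"mse_s{s}" for s in range(1, scale_max + 1)] + list(PRV_COLUMNS)
    raw = np.stack([np.concatenate([ev.values, prv.to_array()])
                    for ev, prv in zip(entropy_vectors, prv_sets)])
    values, mask, medians = impute_columns(raw, medians)
    lab = None if labels is None else np.asarray(labels, dtype=bool)
    return FeatureMatrix(values, mask, raw, cols, lab, medians)


def select_features(matrix: np.ndarray, labels,
                    importance_threshold: float | None = None,
                    seed: int = 0, n_estimators: int = 300) -> np.ndarray:
    """Embedded tree-importance selection.

    Fits a random forest, ranks impurity importances, and keeps the
    columns whose importance reaches the threshold (default: the mean
    importance).  Returns a boolean column mask.
    """
    from sklearn.ensemble import RandomForestClassifier

    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("feature selection needs at least two classes")
    if matrix.size and np.all(matrix.std(axis=0) == 0):
        warnings.warn("all feature columns are constant; nothing to select")
        return np.zeros(matrix.shape[1], dtype=bool)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(matrix, labels)
    imp = rf.feature_importances_
    thr = float(np.mean(imp)) if importance_threshold is None \
        else importance_threshold
    return imp >= thr
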