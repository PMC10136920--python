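"""Core in-memory containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PPGRecord:
    """A single-channel pulse wave.

    Parameters
    ----------
    samples : array-like
        The photoplethysmogram intensity samples ``Y(t)``.
    sampling_rate_hz : float
        Sampling frequency ``N`` in Hz; must be positive.
    """

    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz


@dataclass
class SignalWindow:
    """A fixed-length analysis segment cut from a record.

    ``label`` is the (optional) apnea flag of the labelled minute that covers
    the majority of the window.
    """

    samples: np.ndarray
    start_s: float
    sampling_rate_hz: float
    label: bool | None = None

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s
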