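"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SensorDataset:
    """Multichannel sensor-space recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sensor time series. Arbitrary units; rows are channels.
    fs : float
        Sampling rate in Hz.
    positions : ndarray, shape (n_channels, 3), optional
        Sensor positions in metres (head frame).
    orientations : ndarray, shape (n_channels, 3), optional
        Unit sensing orientations.
    """

    data: np.ndarray
    fs: float
    positions: np.ndarray | None = None
    orientations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("sensor data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "SensorDataset":
        return SensorDataset(data=data, fs=self.fs)


@dataclass
class StateSequence:
    """Per-sample most-probable state labels.

    Labels are 1-based: every entry lies in {1, ..., K}.
    """

    labels: np.ndarray
    K: int
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.labels.size == 0:
            raise ValueError("empty state sequence")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError("labels must lie in {1..K}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def indicator(self, k: int) -> np.ndarray:
        """Binary indicator time course of state ``k`` (1-based)."""
        if not 1 <= k <= self.K:
            raise ValueError(f"state {k} outside 1..{self.K}")
        return (self.labels == k).astype(float)
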