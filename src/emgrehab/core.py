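"""Shared containers and error types.

Conventions used throughout the package:

* signals are ``(n_channels, n_samples)`` float arrays;
* sample indices are 0-based, half-open ``[start, stop)``;
* durations in file headers are seconds (floats), internal indexing is in
  samples (ints);
* classification accuracy is a fraction in ``[0, 1]`` internally and is
  converted to percent only in report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class ConfigurationError(ValueError):
    """Invalid configuration (bad band edges, fold counts, weeks, ...)."""


class DataError(ValueError):
    """Invalid or inconsistent data (NaNs, missing classes, bad boundaries)."""


@dataclass
class EMGRecording:
    """One patient/session/movement multi-channel EMG signal.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``.
    fs:
        Sampling frequency in Hz.
    meta:
        Acquisition metadata. For simulated/recorded sessions this includes
        ``patient_id``, ``group``, ``week``, ``movement`` and
        ``repetitions`` — a list of ``[start, stop)`` sample index pairs, one
        per contraction epoch.
    """

    data: np.ndarray
    fs: float
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, **meta_updates: Any) -> "EMGRecording":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EMGRecording(data=data, fs=self.fs, meta=meta)


@dataclass
class ContractionEpoch:
    """One contraction segment cut out of a recording (rest removed)."""

    recording_id: str
    repetition: int  # 1-based repetition index
    data: np.ndarray  # (n_channels, n_samples)
    start: int  # sample index into the parent recording, 0-based
    stop: int  # half-open
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])


@dataclass
class WindowSet:
    """Overlapping analysis windows cut from one contraction epoch.

    ``windows`` has shape ``(n_windows, n_channels, window_samples)``;
    consecutive window starts differ by exactly ``step_samples`` and every
    window lies fully inside the parent epoch.
    """

    windows: np.ndarray
    window_samples: int
    step_samples: int
    epoch: ContractionEpoch

    @property
    def n_windows(self) -> int:
        return int(self.windows.shape[0])

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step_samples
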