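"""EMG cleaning, contraction epoching, and overlap windowing.

Filters are applied zero-phase (forward-backward) so contraction envelopes are
not phase-distorted; the notch is an IIR notch at 50 Hz with quality factor 30
(about 1.7 Hz rejection bandwidth) and the bandpass is a fourth-order
Butterworth at 20-450 Hz. Epoching is cue-based from the sidecar repetition
boundaries — the acquisition protocol is visually cued with fixed timing, so
no amplitude-onset detection is attempted. Millisecond quantities convert to
samples by flooring (1926 Hz x 250 ms = 481.5 -> 481 samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ConfigurationError, ContractionEpoch, DataError, EMGRecording, WindowSet
from .synth import AcquisitionProtocol


@dataclass(frozen=True)
class PreprocessConfig:
    notch_hz: float = 50.0
    notch_q: float = 30.0
    band_lo_hz: float = 20.0
    band_hi_hz: float = 450.0
    order: int = 4
    window_ms: float = 250.0
    overlap_frac: float = 0.5
    guard_ms: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ConfigurationError("need 0 < band_lo_hz < band_hi_hz")
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ConfigurationError("overlap_frac must lie in [0, 1)")
        if self.window_ms <= 0:
            raise ConfigurationError("window_ms must be positive")


def ms_to_samples(ms: float, fs: float) -> int:
    """Floor-based milliseconds -> samples conversion used package-wide."""
    return int(np.floor(ms * fs / 1000.0))


def _check_finite(rec: EMGRecording) -> None:
    bad = ~np.isfinite(rec.data)
    if bad.any():
        ch, idx = np.argwhere(bad)[0]
        raise DataError(f"non-finite sample in channel {ch} at index {idx}")


def apply_notch(rec: EMGRecording, cfg: PreprocessConfig = PreprocessConfig()) -> EMGRecording:
    """Zero-phase IIR notch at ``cfg.notch_hz`` on every channel.

    Output length equals input length; the applied filter is recorded in the
    metadata under ``filters``.
    """
    _check_finite(rec)
    b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs)
    out = sps.filtfilt(b, a, rec.data, axis=1)
    filters = list(rec.meta.get("filters", [])) + [f"notch{cfg.notch_hz:g}Q{cfg.notch_q:g}"]
    return rec.copy_with(out, filters=filters)


def apply_bandpass(rec: EMGRecording, cfg: PreprocessConfig = PreprocessConfig()) -> EMGRecording:
    """Zero-phase Butterworth bandpass (order ``cfg.order``, 20-450 Hz default)."""
    _check_finite(rec)
    if cfg.band_hi_hz >= rec.fs / 2:
        raise ConfigurationError(
            f"band_hi_hz={cfg.band_hi_hz} must be below Nyquist {rec.fs / 2}")
    sos = sps.butter(cfg.order, [cfg.band_lo_hz, cfg.band_hi_hz],
                     btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    filters = list(rec.meta.get("filters", [])) + [
        f"butter{cfg.order}_{cfg.band_lo_hz:g}-{cfg.band_hi_hz:g}"]
    return rec.copy_with(out, filters=filters)


def preprocess(rec: EMGRecording, cfg: PreprocessConfig = PreprocessConfig()) -> EMGRecording:
    """Notch then bandpass (the two nearly commute for these linear filters)."""
    return apply_bandpass(apply_notch(rec, cfg), cfg)


def extract_epochs(
    rec: EMGRecording,
    protocol: AcquisitionProtocol | None = None,
    guard_ms: float = 250.0,
) -> list[ContractionEpoch]:
    """Cut the cue-timed contraction segments out of a recording.

    Boundaries come from the recording's sidecar metadata (``repetitions``);
    each epoch is trimmed by ``guard_ms`` at both ends to drop the ramp
    transients. Exactly ``protocol.repetitions`` epochs are returned.
    """
    bounds = rec.meta.get("repetitions")
    if bounds is None:
        raise DataError("recording has no repetition boundaries in its sidecar; "
                        "cue-based epoching requires them")
    if protocol is not None and len(bounds) != protocol.repetitions:
        raise DataError(f"expected {protocol.repetitions} repetitions, "
                        f"sidecar lists {len(bounds)}")
    guard = ms_to_samples(guard_ms, rec.fs)
    rec_id = "{}_w{}_{}".format(rec.meta.get("patient_id", "?"),
                                rec.meta.get("week", "?"),
                                rec.meta.get("movement", "?"))
    epochs: list[ContractionEpoch] = []
    prev_stop = -1
    for r, (start, stop) in enumerate(bounds, start=1):
        if not (0 <= start < stop <= rec.n_samples):
            raise DataError(f"repetition {r} bounds [{start}, {stop}) fall outside "
                            f"the {rec.n_samples}-sample recording")
        if start < prev_stop:
            raise DataError(f"repetition {r} overlaps the previous one")
        prev_stop = stop
        a, b = start + guard, stop - guard
        if b - a < 1:
            raise DataError(f"guard_ms={guard_ms} leaves repetition {r} empty")
        epochs.append(ContractionEpoch(
            recording_id=rec_id, repetition=r,
            data=rec.data[:, a:b], start=a, stop=b,
            meta=dict(rec.meta),
        ))
    return epochs


def make_windows(
    epoch: ContractionEpoch,
    cfg: PreprocessConfig,
    fs: float,
) -> WindowSet:
    """Segment one epoch into overlapping fixed-length windows.

    ``window = floor(window_ms * fs / 1000)``, ``step = floor(window * (1 -
    overlap_frac))``; the trailing partial window is discarded. For a
    9630-sample epoch at 1926 Hz with 250 ms / 50% this yields 39 windows of
    481 samples stepping by 240.
    """
    window = ms_to_samples(cfg.window_ms, fs)
    step = max(1, int(np.floor(window * (1.0 - cfg.overlap_frac))))
    L = epoch.n_samples
    if L < window:
        raise DataError(f"epoch of {L} samples is shorter than one "
                        f"{window}-sample window")
    count = (L - window) // step + 1
    idx = np.arange(count)[:, None] * step + np.arange(window)[None, :]
    windows = epoch.data[:, idx]  # (channels, count, window)
    windows = np.moveaxis(windows, 0, 1)  # (count, channels, window)
    return WindowSet(windows=np.ascontiguousarray(windows),
                     window_samples=window, step_samples=step, epoch=epoch)
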