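"""Time- and frequency-domain EMG feature bank.

Fourteen time-domain features — root mean square (RMS), mean absolute value
(MAV), integrated EMG (IEMG), slope sign change (SSC), zero crossing (ZC),
peak-to-peak (PTP), variance (VAR), standard deviation (SD), waveform length
(WL), cardinality (CARD), interquartile range (IQR), kurtosis (KURT), average
energy (AENG), average amplitude change (AAC) — plus mean and median frequency
(MNF, MDF) of the power spectrum, computed per window per channel.

Definitions (x of length N):

* RMS = sqrt(sum x_i^2 / N); AENG = sum x_i^2 / N (so AENG = RMS^2)
* MAV = sum |x_i| / N; IEMG = sum |x_i| (so IEMG = N * MAV)
* SSC = #{1 < i < N : (x_i - x_{i-1})(x_i - x_{i+1}) > ssc_threshold}
* ZC  = #{i : sign(x_i) != sign(x_{i+1}) and |x_i - x_{i+1}| >= zc_threshold}
* PTP = max - min; VAR = sum (x - mean)^2 / (N - 1); SD = sqrt(VAR)
* WL  = sum |x_{i+1} - x_i|; AAC = WL / (N - 1)
* CARD = number of distinct values after sorting, merging consecutive sorted
  values that differ by at most cardinality_tol * SD
* IQR = Q3 - Q1; KURT = excess kurtosis (Fisher) by default
* MNF = sum f P(f) / sum P(f); MDF = smallest f with cumulative power >= half
  the total (linear interpolation between PSD bins)

VAR/SD use the N-1 (sample) denominator while AENG/RMS use N; ZC/SSC deadband
thresholds default to 0; the PSD defaults to Welch (256-sample segments, 50%
overlap) with a raw-periodogram mode retained for oracle comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .core import ConfigurationError, DataError, WindowSet

log = logging.getLogger(__name__)

#: Fixed feature order used in every table and serialized header.
FEATURE_NAMES = (
    "rms", "mav", "iemg", "ssc", "zc", "ptp", "var", "sd",
    "wl", "card", "iqr", "kurt", "aeng", "aac", "mnf", "mdf",
)

LABEL_COLUMNS = ("patient_id", "group", "week", "movement", "repetition", "window_idx")


@dataclass(frozen=True)
class FeatureSpec:
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    cardinality_tol: float = 1e-4  # as a fraction of the window SD
    iqr_method: str = "linear"
    kurtosis_convention: str = "fisher"  # or "pearson"
    psd_method: str = "welch"  # or "periodogram"
    psd_nperseg: int = 256
    psd_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.zc_threshold < 0 or self.ssc_threshold < 0:
            raise ConfigurationError("deadband thresholds must be >= 0")
        if self.kurtosis_convention not in ("fisher", "pearson"):
            raise ConfigurationError("kurtosis_convention must be fisher or pearson")
        if self.psd_method not in ("welch", "periodogram"):
            raise ConfigurationError("psd_method must be welch or periodogram")


def td_features(x: np.ndarray, spec: FeatureSpec = FeatureSpec()) -> dict[str, float]:
    """The 14 time-domain features of one single-channel window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise DataError(f"window of {n} samples is too short (need >= 4)")
    if not np.all(np.isfinite(x)):
        raise DataError("window contains non-finite samples")

    aeng = float(np.mean(x * x))
    rms = float(np.sqrt(aeng))
    iemg = float(np.sum(np.abs(x)))
    mav = iemg / n
    d = np.diff(x)
    wl = float(np.sum(np.abs(d)))
    aac = wl / (n - 1)
    var = float(np.var(x, ddof=1))
    sd = float(np.sqrt(var))
    ptp = float(np.max(x) - np.min(x))
    ssc = int(np.count_nonzero(
        (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > spec.ssc_threshold))
    s = np.sign(x)
    zc = int(np.count_nonzero((s[:-1] != s[1:]) & (np.abs(d) >= spec.zc_threshold)))
    xs = np.sort(x)
    tol = spec.cardinality_tol * sd
    card = int(1 + np.count_nonzero(np.diff(xs) > tol))
    q1, q3 = np.percentile(x, [25.0, 75.0], method=spec.iqr_method)
    iqr = float(q3 - q1)
    if sd == 0.0:
        # degenerate-moment rule: kurtosis of a constant window is set to 0
        log.warning("constant window: kurtosis defined as 0")
        kurt = 0.0
    else:
        kurt = float(spstats.kurtosis(
            x, fisher=spec.kurtosis_convention == "fisher", bias=True))
    return {
        "rms": rms, "mav": mav, "iemg": iemg, "ssc": ssc, "zc": zc,
        "ptp": ptp, "var": var, "sd": sd, "wl": wl, "card": card,
        "iqr": iqr, "kurt": kurt, "aeng": aeng, "aac": aac,
    }


def _psd(x: np.ndarray, fs: float, spec: FeatureSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.psd_method == "welch":
        nper = min(spec.psd_nperseg, x.size)
        return sps.welch(x, fs=fs, nperseg=nper,
                         noverlap=int(nper * spec.psd_overlap_frac))
    return sps.periodogram(x, fs=fs)


def fd_features(x: np.ndarray, fs: float,
                spec: FeatureSpec = FeatureSpec()) -> dict[str, float]:
    """Mean and median frequency of one single-channel window."""
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        log.warning("all-zero window: MNF and MDF defined as 0")
        return {"mnf": 0.0, "mdf": 0.0}
    f, p = _psd(x, fs, spec)
    total = float(np.sum(p))
    if total <= 0:
        log.warning("zero-power spectrum: MNF and MDF defined as 0")
        return {"mnf": 0.0, "mdf": 0.0}
    mnf = float(np.sum(f * p) / total)
    c = np.cumsum(p)
    half = total / 2.0
    i = int(np.searchsorted(c, half))
    if i == 0:
        mdf = float(f[0] * half / c[0]) if c[0] > 0 else float(f[0])
    else:
        # linear interpolation inside bin i
        mdf = float(f[i - 1] + (half - c[i - 1]) / (c[i] - c[i - 1]) * (f[i] - f[i - 1]))
    return {"mnf": mnf, "mdf": mdf}


def window_features(window: np.ndarray, fs: float,
                    spec: FeatureSpec = FeatureSpec()) -> dict[str, float]:
    """All 16 features for every channel of one ``(channels, samples)`` window.

    Keys are ``<feature>_ch<k>`` with 1-based channel numbers, ordered by
    :data:`FEATURE_NAMES` then channel.
    """
    n_ch = window.shape[0]
    per_channel = []
    for c in range(n_ch):
        vals = td_features(window[c], spec)
        vals.update(fd_features(window[c], fs, spec))
        per_channel.append(vals)
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        for c in range(n_ch):
            out[f"{name}_ch{c + 1}"] = per_channel[c][name]
    return out


def build_feature_table(window_sets: Iterable[WindowSet], fs: float,
                        spec: FeatureSpec = FeatureSpec()) -> pd.DataFrame:
    """Assemble the labelled windows x (features x channels) table.

    One row per window; label columns (patient, group, week, movement,
    repetition, window index) followed by the 16 x n_channels feature columns
    in fixed order. Rows are sorted deterministically by
    (patient, week, movement, repetition, window index).
    """
    rows = []
    n_ch = None
    for ws in window_sets:
        meta = ws.epoch.meta
        if n_ch is None:
            n_ch = ws.windows.shape[1]
        elif ws.windows.shape[1] != n_ch:
            raise ConfigurationError("window sets have heterogeneous channel counts")
        for w_idx in range(ws.n_windows):
            row = {
                "patient_id": meta.get("patient_id"),
                "group": meta.get("group"),
                "week": meta.get("week"),
                "movement": meta.get("movement"),
                "repetition": ws.epoch.repetition,
                "window_idx": w_idx,
            }
            row.update(window_features(ws.windows[w_idx], fs, spec))
            rows.append(row)
    if not rows:
        raise DataError("no windows supplied")
    df = pd.DataFrame(rows)
    df = df.sort_values(["patient_id", "week", "movement", "repetition", "window_idx"],
                        kind="mergesort").reset_index(drop=True)
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a table, in their fixed order."""
    return [c for c in df.columns if c not in LABEL_COLUMNS]
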