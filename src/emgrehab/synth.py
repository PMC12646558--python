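"""Synthetic two-arm longitudinal cohort generator (EMG + clinical scores).

No patient data are distributed with this package. This module generates a
surrogate cohort with the statistical structure the downstream analysis
assumes: two groups with different recovery rates, four assessment weeks, a
cue-timed rest/contraction protocol on five forearm muscles, and clinical
scores (FMA-UE, ARAT, BBT) monotonically linked to the same latent recovery
variable that drives EMG separability.

Model sketch
------------
Each patient carries a 7x5 non-negative *activation matrix* ``A`` (movements x
channels) drawn once and reused across weeks. Motor recovery is a latent
*separability* ``lambda(w) = min(plateau, lambda0 + gain_per_week * w)`` in
``[0, 1]``. At week ``w`` the effective pattern for movement ``m`` is the
blend ``A_eff = (1 - lambda) * Abar + lambda * A[m]`` where ``Abar`` is the
movement-averaged (confusable) pattern: at ``lambda = 0`` every movement looks
the same, at ``lambda = 1`` patterns are fully distinct. Each channel's signal
is an amplitude-modulated band-limited (20-450 Hz) Gaussian carrier under a
trapezoidal contraction envelope, plus 50 Hz line interference, low-frequency
drift, and white noise. Recovery also reduces per-repetition multiplicative
jitter (scale ``jitter0 * jitter_decay ** lambda``) and raises overall
activation strength by ``1 + amp_per_lambda * lambda``, so classification
accuracy, EMG amplitude features, and clinical scores all respond to the one
latent.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import ConfigurationError, DataError, EMGRecording

MOVEMENTS = (
    "flexion",
    "extension",
    "opening",
    "closing",
    "pinch",
    "pronation",
    "supination",
)
CHANNELS = (
    "extensor digitorum communis",
    "flexor digitorum superficialis",
    "supinator",
    "pronator teres",
    "dorsal interossei",
)

FMA_UE_MAX = 66
ARAT_MAX = 57


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Cue-timed acquisition protocol: rest, then contract, repeated.

    Defaults mirror a wireless surface-EMG setup sampling at 1926 Hz with
    5 s rest / 5 s contraction, three repetitions per movement, seven hand
    movements and five forearm muscles.
    """

    fs_hz: float = 1926.0
    rest_s: float = 5.0
    contract_s: float = 5.0
    repetitions: int = 3
    movements: tuple[str, ...] = MOVEMENTS
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.rest_s <= 0 or self.contract_s <= 0:
            raise ConfigurationError("protocol durations and fs must be positive")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def session_samples(self) -> int:
        """Samples in one movement session: repetitions x (rest + contract)."""
        per_rep = self.rest_s + self.contract_s
        return int(round(self.repetitions * per_rep * self.fs_hz))

    def repetition_bounds(self) -> list[tuple[int, int]]:
        """0-based half-open sample bounds of each contraction segment."""
        fs = self.fs_hz
        bounds = []
        for r in range(self.repetitions):
            t0 = r * (self.rest_s + self.contract_s) + self.rest_s
            start = int(round(t0 * fs))
            stop = int(round((t0 + self.contract_s) * fs))
            bounds.append((start, stop))
        return bounds


@dataclass(frozen=True)
class RecoveryModel:
    """Group-level recovery trajectory of the separability latent.

    ``lambda(w) = min(plateau, lambda0 + gain_per_week * w)``, non-decreasing
    and bounded in [0, 1]. ``jitter0`` is the baseline within-class
    multiplicative jitter scale, reduced by the factor
    ``jitter_decay ** lambda``. ``lambda0_sd``, ``gain_rel_sd`` and
    ``plateau_sd`` control between-patient heterogeneity of the latent
    (patients start, recover, and saturate at different levels), which is
    what makes within-group EMG-clinical correlations estimable — without a
    spread on the ceiling, every patient in a group would sit at exactly the
    same latent once the trajectory saturates.
    """

    lambda0: float = 0.35
    gain_per_week: float = 0.063
    plateau: float = 0.76
    jitter0: float = 0.7
    jitter_decay: float = 0.15
    lambda0_sd: float = 0.05
    gain_rel_sd: float = 0.18
    plateau_sd: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda0 <= 1.0 and 0.0 < self.plateau <= 1.0):
            raise ConfigurationError("lambda0 and plateau must lie in [0, 1]")
        if self.gain_per_week < 0:
            raise ConfigurationError("gain_per_week must be non-negative")

    def separability(self, week: float, lambda0: float | None = None,
                     gain: float | None = None,
                     plateau: float | None = None) -> float:
        lam0 = self.lambda0 if lambda0 is None else lambda0
        g = self.gain_per_week if gain is None else gain
        cap = self.plateau if plateau is None else plateau
        return float(np.clip(min(cap, lam0 + g * week), 0.0, 1.0))

    def jitter_scale(self, lam: float) -> float:
        return float(self.jitter0 * self.jitter_decay ** lam)


@dataclass(frozen=True)
class ClinicalLink:
    """Monotone link from the recovery latent to clinical scores.

    ``FMA-UE = clip(round(FMA0 + beta_fma * lambda * (66 - FMA0) + eps))``,
    ARAT analogously into [0, 57], and
    ``BBT = clip(round(BBT0 + beta_bbt * lambda * bbt_scale + eps))`` with
    small Gaussian measurement noise ``eps ~ N(0, eps_sd^2)``.
    """

    beta_fma: float = 1.0
    beta_arat: float = 1.0
    beta_bbt: float = 1.0
    bbt_scale: float = 35.0
    eps_sd: float = 1.0


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient: fixed traits reused across all weeks."""

    patient_id: str
    group: str
    activation: np.ndarray  # (n_movements, n_channels) non-negative gains
    baseline_clinical: tuple[int, int, int]  # (FMA-UE, ARAT, BBT)
    noise_scale: float
    lambda0: float  # patient-specific latent intercept
    gain_per_week: float  # patient-specific latent slope
    plateau: float  # patient-specific recovery ceiling
    rates: RecoveryModel

    def separability(self, week: float) -> float:
        return self.rates.separability(week, self.lambda0, self.gain_per_week,
                                       self.plateau)


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration of the synthetic two-arm cohort."""

    n_per_group: int = 26
    groups: tuple[str, str] = ("experimental", "control")
    weeks: tuple[int, ...] = (0, 4, 6, 9)
    seed: int = 0
    snr_db: float = 18.0
    line_amp: float = 0.05
    drift_amp: float = 0.08
    amp_per_lambda: float = 1.5
    rates: dict[str, RecoveryModel] = field(default_factory=lambda: {
        "experimental": RecoveryModel(gain_per_week=0.063, plateau=0.76),
        "control": RecoveryModel(gain_per_week=0.05, plateau=0.68),
    })
    clinical: ClinicalLink = field(default_factory=ClinicalLink)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ConfigurationError("weeks must be strictly increasing")
        for g in self.groups:
            if g not in self.rates:
                raise ConfigurationError(f"no RecoveryModel for group {g!r}")


@dataclass
class Cohort:
    """Simulated two-arm study: config plus per-patient profiles."""

    config: CohortConfig
    patients: list[PatientProfile]

    def __len__(self) -> int:
        return len(self.patients)

    def by_group(self, group: str) -> list[PatientProfile]:
        return [p for p in self.patients if p.group == group]


def _stream(seed: int, *tokens) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from string/int tokens."""
    key = "|".join(str(t) for t in tokens)
    crc = zlib.crc32(key.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, crc]))


def make_cohort(config: CohortConfig, protocol: AcquisitionProtocol | None = None) -> Cohort:
    """Draw patient profiles for both arms.

    Deterministic for a fixed ``config.seed``; activation matrices and
    baseline clinical scores are drawn once per patient and reused across
    weeks. Baseline FMA-UE respects the inclusion band [25, 55].
    """
    protocol = protocol or AcquisitionProtocol()
    n_mov, n_ch = len(protocol.movements), protocol.n_channels
    patients: list[PatientProfile] = []
    for gi, group in enumerate(config.groups):
        rates = config.rates[group]
        for pi in range(config.n_per_group):
            pid = f"{group[:3]}{pi + 1:03d}"
            rng = _stream(config.seed, "profile", group, pid)
            activation = rng.uniform(0.2, 1.5, size=(n_mov, n_ch))
            # hold the overall activation level comparable across patients
            # (electrode gain is a nuisance; recovery should drive amplitude)
            activation *= 0.85 / activation.mean()
            # inclusion band [25, 55]; centred like a moderate-impairment cohort
            fma0 = int(np.clip(round(rng.normal(40.0, 6.0)), 25, 55))
            arat0 = int(np.clip(round(0.55 * fma0 + rng.normal(0, 3)), 0, ARAT_MAX))
            bbt0 = int(np.clip(round(0.35 * fma0 + rng.normal(0, 3)), 0, None))
            lam0 = float(np.clip(rng.normal(rates.lambda0, rates.lambda0_sd), 0.0, 1.0))
            gain = float(max(0.0, rates.gain_per_week
                             * (1.0 + rates.gain_rel_sd * rng.standard_normal())))
            cap = float(np.clip(rng.normal(rates.plateau, rates.plateau_sd),
                                lam0, 1.0))
            patients.append(PatientProfile(
                patient_id=pid,
                group=group,
                activation=activation,
                baseline_clinical=(fma0, arat0, bbt0),
                noise_scale=1.0,
                lambda0=lam0,
                gain_per_week=gain,
                plateau=cap,
                rates=rates,
            ))
    return Cohort(config=config, patients=patients)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    hi = min(hi, 0.499 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y ** 2))
    return y / rms if rms > 0 else y


def _drift(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS low-frequency (<2 Hz) motion-artifact surrogate."""
    x = rng.standard_normal(n)
    sos = sps.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y ** 2))
    return y / rms if rms > 0 else y


def _envelope(protocol: AcquisitionProtocol, ramp_s: float = 0.25) -> np.ndarray:
    """Trapezoidal contraction envelope: 0 at rest, ramped plateaus at 1."""
    n = protocol.session_samples
    fs = protocol.fs_hz
    env = np.zeros(n)
    ramp = max(1, int(round(ramp_s * fs)))
    for start, stop in protocol.repetition_bounds():
        seg = min(stop, n) - start
        e = np.ones(seg)
        r = min(ramp, seg // 2)
        e[:r] = np.linspace(0.0, 1.0, r, endpoint=False)
        e[seg - r:] = np.linspace(1.0, 0.0, r + 1)[1:]
        env[start:start + seg] = e
    return env


def simulate_emg_session(
    profile: PatientProfile,
    week: float,
    movement: str,
    protocol: AcquisitionProtocol,
    config: CohortConfig,
) -> EMGRecording:
    """Simulate one patient/week/movement multi-channel EMG session.

    Per channel ``c``::

        x_c(t) = g * A_eff[m, c] * jitter_rep * e(t) * carrier_c(t)
                 + drift_amp * d(t) + line_amp * sin(2*pi*50*t + phi) + noise

    with ``A_eff = (1 - lam) * Abar + lam * A[m]``, ``g = 1 +
    amp_per_lambda * lam``, trapezoidal envelope ``e``, unit-RMS 20-450 Hz
    Gaussian carrier, and white noise at ``snr_db`` below the mean activation.
    The RNG stream is derived by hashing (seed, patient, week, movement), so
    any subset of the cohort regenerates identically.
    """
    if movement not in protocol.movements:
        raise DataError(f"unknown movement {movement!r}; expected one of {protocol.movements}")
    rng = _stream(config.seed, "emg", profile.patient_id, week, movement)
    m = protocol.movements.index(movement)
    lam = profile.separability(week)
    a_bar = profile.activation.mean(axis=0)
    a_eff = (1.0 - lam) * a_bar + lam * profile.activation[m]
    gain = 1.0 + config.amp_per_lambda * lam

    n = protocol.session_samples
    fs = protocol.fs_hz
    t = np.arange(n) / fs
    env = _envelope(protocol)
    bounds = protocol.repetition_bounds()

    jit_sd = profile.rates.jitter_scale(lam)
    # per-repetition, per-channel multiplicative jitter (kept positive)
    jitter = np.clip(1.0 + jit_sd * rng.standard_normal((len(bounds), protocol.n_channels)),
                     0.05, None)
    rep_gain = np.ones(n)  # per-sample repetition jitter factor template
    noise_sd = profile.noise_scale * float(a_eff.mean()) * 10 ** (-config.snr_db / 20)

    data = np.empty((protocol.n_channels, n))
    phi = rng.uniform(0, 2 * np.pi, size=protocol.n_channels)
    for c in range(protocol.n_channels):
        carrier = _bandlimited_noise(rng, n, fs, 20.0, 450.0)
        rep_gain[:] = 1.0
        for r, (start, stop) in enumerate(bounds):
            rep_gain[start:stop] = jitter[r, c]
        x = gain * a_eff[c] * rep_gain * env * carrier
        x = x + config.drift_amp * _drift(rng, n, fs)
        x = x + config.line_amp * np.sin(2 * np.pi * 50.0 * t + phi[c])
        x = x + noise_sd * rng.standard_normal(n)
        data[c] = x

    meta = {
        "patient_id": profile.patient_id,
        "group": profile.group,
        "week": week,
        "movement": movement,
        "fs_hz": fs,
        "repetitions": [[int(a), int(b)] for a, b in bounds],
        "separability": lam,
    }
    return EMGRecording(data=data, fs=fs, meta=meta)


def simulate_clinical_scores(
    profile: PatientProfile,
    week: float,
    config: CohortConfig,
    noiseless: bool = False,
) -> dict:
    """Clinical scores (FMA-UE, ARAT, BBT) at ``week`` for one patient.

    Scores are non-decreasing in expectation with the recovery latent and are
    clipped into their instrument ranges (FMA-UE 0-66, ARAT 0-57, BBT >= 0).
    """
    link = config.clinical
    rng = _stream(config.seed, "clinical", profile.patient_id, week)
    lam = profile.separability(week)
    fma0, arat0, bbt0 = profile.baseline_clinical
    eps = np.zeros(3) if noiseless else rng.normal(0.0, link.eps_sd, size=3)
    fma = int(np.clip(round(fma0 + link.beta_fma * lam * (FMA_UE_MAX - fma0) + eps[0]),
                      0, FMA_UE_MAX))
    arat = int(np.clip(round(arat0 + link.beta_arat * lam * (ARAT_MAX - arat0) + eps[1]),
                       0, ARAT_MAX))
    bbt = int(np.clip(round(bbt0 + link.beta_bbt * lam * link.bbt_scale + eps[2]), 0, None))
    return {
        "patient_id": profile.patient_id,
        "group": profile.group,
        "week": week,
        "fma_ue": fma,
        "arat": arat,
        "bbt": bbt,
    }


def generate_dataset(cohort: Cohort, protocol: AcquisitionProtocol,
                     out_dir: str | Path) -> dict:
    """Write the full cohort to disk and return (and persist) a manifest.

    One EMG CSV + JSON sidecar per (patient, week, movement), one clinical
    score table, and ``manifest.json`` listing every file with its SHA-256
    checksum, the generator version and the master seed.
    """
    from . import io as eio  # local import to avoid a cycle

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise DataError(f"cannot create output directory {out}: {exc}") from exc

    files: list[dict] = []
    clinical_rows = []
    for profile in cohort.patients:
        for week in cohort.config.weeks:
            clinical_rows.append(simulate_clinical_scores(profile, week, cohort.config))
            for movement in protocol.movements:
                rec = simulate_emg_session(profile, week, movement, protocol, cohort.config)
                stem = f"{profile.patient_id}_w{week}_{movement}"
                csv_path = out / f"{stem}.csv"
                sidecar_path = out / f"{stem}.json"
                eio.write_emg(rec, csv_path, sidecar_path)
                files.append({"path": csv_path.name, "role": "emg",
                              "sha256": _sha256(csv_path)})
                files.append({"path": sidecar_path.name, "role": "sidecar",
                              "sha256": _sha256(sidecar_path)})
    clin_path = out / "clinical_scores.csv"
    eio.write_clinical(clinical_rows, clin_path)
    files.append({"path": clin_path.name, "role": "clinical", "sha256": _sha256(clin_path)})

    from . import __version__

    manifest = {
        "generator_version": __version__,
        "seed": cohort.config.seed,
        "n_patients": len(cohort),
        "weeks": list(cohort.config.weeks),
        "movements": list(protocol.movements),
        "n_recordings": sum(1 for f in files if f["role"] == "emg"),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
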