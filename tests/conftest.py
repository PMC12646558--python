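"""Shared fixtures: scaled-down protocols and synthetic patient tables.

The full acquisition protocol (5 s rest / 5 s contraction, 1926 Hz) is used
only where the test is about its arithmetic; everything that just needs a
working patient-week table runs on a shortened protocol (1 s rest / 2 s
contraction) that preserves the pipeline structure while keeping the suite
fast.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import emgrehab as er
from emgrehab.preprocess import preprocess


@pytest.fixture(scope="session")
def full_protocol() -> er.AcquisitionProtocol:
    return er.AcquisitionProtocol()


@pytest.fixture(scope="session")
def short_protocol() -> er.AcquisitionProtocol:
    return er.AcquisitionProtocol(rest_s=1.0, contract_s=2.0)


def make_fixed_lambda_config(lam: float, seed: int, *, jitter0: float = 0.7,
                             jitter_decay: float = 0.15, snr_db: float = 18.0,
                             line_amp: float = 0.05, drift_amp: float = 0.08,
                             n_per_group: int = 2) -> er.CohortConfig:
    """Cohort config whose latent is pinned at ``lam`` for every week."""
    rates = er.RecoveryModel(lambda0=lam, gain_per_week=0.0, plateau=1.0,
                             jitter0=jitter0, jitter_decay=jitter_decay,
                             lambda0_sd=0.0, gain_rel_sd=0.0, plateau_sd=0.0)
    return er.CohortConfig(n_per_group=n_per_group, seed=seed, snr_db=snr_db,
                           line_amp=line_amp, drift_amp=drift_amp,
                           rates={"experimental": rates, "control": rates})


def patient_week_table(lam: float, seed: int, protocol: er.AcquisitionProtocol,
                       **config_kwargs) -> "pd.DataFrame":
    """Feature table of one synthetic patient at a fixed separability."""
    cfg = make_fixed_lambda_config(lam, seed, **config_kwargs)
    cohort = er.make_cohort(cfg, protocol)
    patient = cohort.patients[0]
    window_sets = []
    pcfg = er.PreprocessConfig()
    for movement in protocol.movements:
        rec = preprocess(er.simulate_emg_session(patient, 0, movement, protocol, cfg))
        for epoch in er.extract_epochs(rec, protocol, pcfg.guard_ms):
            window_sets.append(er.make_windows(epoch, pcfg, rec.fs))
    return er.build_feature_table(window_sets, protocol.fs_hz)


@pytest.fixture(scope="session")
def separable_table(short_protocol):
    """A noiseless, jitter-free, fully separable patient-week table."""
    return patient_week_table(1.0, seed=7, protocol=short_protocol,
                              jitter0=0.0, snr_db=80.0, line_amp=0.0,
                              drift_amp=0.0)


@pytest.fixture(scope="session")
def tiny_run_config(tmp_path_factory):
    """A miniature end-to-end run configuration (n=3 per group, 2 weeks)."""
    base = tmp_path_factory.mktemp("tiny_run")
    data = {
        "seed": 11,
        "dataset_dir": str(base / "dataset"),
        "out_dir": str(base / "out"),
        "cohort": {"n_per_group": 3, "weeks": [0, 9]},
        "protocol": {"rest_s": 1.0, "contract_s": 2.0,
                     "movements": ["flexion", "extension"]},
        "classifiers": ["knn"],
        "cv": {"folds": 3},
    }
    from emgrehab.pipeline import RunConfig

    return RunConfig.from_dict(data)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
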