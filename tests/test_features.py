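"""Feature bank: hand-computed examples, algebraic identities, naive oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

import emgrehab as er
from emgrehab.core import ConfigurationError, DataError
from emgrehab.features import (FEATURE_NAMES, fd_features, feature_columns,
                               td_features, window_features)

FS = 1926.0


# --- independent naive reimplementation, written directly from the formulas


def naive_td(x):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    rms = math.sqrt(sum(v * v for v in x) / n)
    iemg = sum(abs(v) for v in x)
    mav = iemg / n
    ssc = sum(1 for i in range(1, n - 1)
              if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0)

    def sign(v):
        return (v > 0) - (v < 0)

    zc = sum(1 for i in range(n - 1) if sign(x[i]) != sign(x[i + 1]))
    ptp = max(x) - min(x)
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sd = math.sqrt(var)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(n - 1))
    aac = wl / (n - 1)
    xs = sorted(x)
    tol = 1e-4 * sd
    card = 1 + sum(1 for i in range(n - 1) if xs[i + 1] - xs[i] > tol)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = float(q3 - q1)
    if sd == 0:
        kurt = 0.0
    else:
        m2 = sum((v - mean) ** 2 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        kurt = m4 / m2 ** 2 - 3.0
    aeng = sum(v * v for v in x) / n
    return {"rms": rms, "mav": mav, "iemg": iemg, "ssc": ssc, "zc": zc,
            "ptp": ptp, "var": var, "sd": sd, "wl": wl, "card": card,
            "iqr": iqr, "kurt": kurt, "aeng": aeng, "aac": aac}


class TestHandValues:
    def test_alternating_unit_window(self):
        f = td_features([1, -1, 1, -1])
        assert f["rms"] == 1 and f["mav"] == 1 and f["iemg"] == 4
        assert f["zc"] == 3 and f["ptp"] == 2 and f["wl"] == 6 and f["aac"] == 2

    def test_slope_sign_changes(self):
        assert td_features([0, 2, 0, 2])["ssc"] == 2

    def test_constant_window_degenerate(self):
        f = td_features([3.0, 3.0, 3.0, 3.0])
        assert f["zc"] == 0 and f["ssc"] == 0 and f["wl"] == 0
        assert f["var"] == 0 and f["ptp"] == 0 and f["rms"] == 3.0
        assert f["kurt"] == 0.0 and f["card"] == 1

    def test_short_window_rejected(self):
        with pytest.raises(DataError):
            td_features([1, 2, 3])

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            td_features([1, 2, np.nan, 4])


class TestOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_on_random_integer_windows(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 17))
        x = rng.integers(-5, 6, size=n).astype(float)
        ours = td_features(x)
        ref = naive_td(x)
        for name, val in ref.items():
            assert ours[name] == pytest.approx(val, rel=1e-12, abs=1e-12), name

    def test_bulk_identities_thousand_windows(self):
        """IEMG=N*MAV, AENG=RMS^2, VAR=SD^2, WL=(N-1)*AAC on 1000 windows."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(4, 64))
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            f = td_features(x)
            assert f["iemg"] == pytest.approx(n * f["mav"], rel=1e-12)
            assert f["aeng"] == pytest.approx(f["rms"] ** 2, rel=1e-12)
            assert f["var"] == pytest.approx(f["sd"] ** 2, rel=1e-12)
            assert f["wl"] == pytest.approx((n - 1) * f["aac"], rel=1e-12)


SCALE_LINEAR = ("rms", "mav", "iemg", "ptp", "sd", "wl", "iqr", "aac")
SCALE_QUADRATIC = ("var", "aeng")
SCALE_INVARIANT = ("ssc", "zc", "kurt", "card")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(-10, 10, allow_nan=False), min_size=6, max_size=40),
    a=st.floats(0.1, 50.0),
)
def test_amplitude_scaling_property(x, a):
    x = np.asarray(x)
    if np.ptp(x) == 0:
        x = x + np.linspace(0, 1, x.size)  # avoid the degenerate constant case
    f0 = td_features(x)
    f1 = td_features(a * x)
    for name in SCALE_LINEAR:
        assert f1[name] == pytest.approx(a * f0[name], rel=1e-9, abs=1e-12)
    for name in SCALE_QUADRATIC:
        assert f1[name] == pytest.approx(a * a * f0[name], rel=1e-9, abs=1e-12)
    for name in SCALE_INVARIANT:
        assert f1[name] == pytest.approx(f0[name], rel=1e-9, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(x=st.lists(st.floats(-10, 10, allow_nan=False), min_size=6, max_size=40))
def test_sign_flip_leaves_all_features_unchanged(x):
    x = np.asarray(x)
    f0, f1 = td_features(x), td_features(-x)
    for name in f0:
        assert f1[name] == pytest.approx(f0[name], rel=1e-9, abs=1e-12), name


class TestFrequencyDomain:
    def test_pure_tone_mnf_mdf(self):
        # 100.3125 Hz sits exactly on a periodogram bin for N=1926*2
        n = int(2 * FS)
        t = np.arange(n) / FS
        freq = 100 * FS / n * 2  # on-bin frequency near 100 Hz
        x = np.sin(2 * np.pi * freq * t)
        spec = er.FeatureSpec(psd_method="periodogram")
        f = fd_features(x, FS, spec)
        bin_width = FS / n
        assert abs(f["mnf"] - freq) <= bin_width
        assert abs(f["mdf"] - freq) <= bin_width

    def test_white_noise_mean_frequency_near_quarter_fs(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200_000)
        f = fd_features(x, FS, er.FeatureSpec())
        assert f["mnf"] == pytest.approx(FS / 4, rel=0.10)

    def test_all_zero_window_is_zero(self):
        f = fd_features(np.zeros(481), FS)
        assert f == {"mnf": 0.0, "mdf": 0.0}

    def test_mnf_mdf_within_nyquist(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.standard_normal(481)
            f = fd_features(x, FS)
            assert 0 <= f["mnf"] <= FS / 2
            assert 0 <= f["mdf"] <= FS / 2

    def test_scaling_leaves_spectral_features_unchanged(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(481)
        f0 = fd_features(x, FS)
        f1 = fd_features(7.5 * x, FS)
        assert f1["mnf"] == pytest.approx(f0["mnf"], rel=1e-9)
        assert f1["mdf"] == pytest.approx(f0["mdf"], rel=1e-9)


class TestFeatureTable:
    def test_row_count_and_columns(self, separable_table, short_protocol):
        # 7 movements x 3 repetitions x windows-per-epoch rows
        ws_per_epoch = separable_table.groupby(
            ["movement", "repetition"]).size().unique()
        assert len(ws_per_epoch) == 1
        assert len(separable_table) == 7 * 3 * ws_per_epoch[0]
        cols = feature_columns(separable_table)
        assert len(cols) == 16 * short_protocol.n_channels
        # fixed order: feature-major, channel-minor
        assert cols[:5] == [f"rms_ch{c}" for c in range(1, 6)]
        assert [c.rsplit("_ch", 1)[0] for c in cols[::5]] == list(FEATURE_NAMES)

    def test_cells_match_standalone_recompute(self, separable_table, short_protocol):
        """Recomputing a row's features from its window reproduces the cells."""
        import emgrehab as er
        from conftest import make_fixed_lambda_config
        from emgrehab.preprocess import preprocess

        cfg = make_fixed_lambda_config(1.0, seed=7, jitter0=0.0, snr_db=80.0,
                                       line_amp=0.0, drift_amp=0.0)
        patient = er.make_cohort(cfg, short_protocol).patients[0]
        rec = preprocess(er.simulate_emg_session(
            patient, 0, "flexion", short_protocol, cfg))
        epoch = er.extract_epochs(rec, short_protocol, 250.0)[0]
        ws = er.make_windows(epoch, er.PreprocessConfig(), rec.fs)
        row = separable_table[
            (separable_table["movement"] == "flexion")
            & (separable_table["repetition"] == 1)
            & (separable_table["window_idx"] == 2)].iloc[0]
        recomputed = window_features(ws.windows[2], short_protocol.fs_hz)
        for key, val in recomputed.items():
            assert row[key] == val, key

    def test_table_roundtrips_through_csv(self, separable_table, tmp_path):
        path = tmp_path / "features.csv"
        separable_table.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        cols = feature_columns(separable_table)
        assert np.allclose(back[cols].to_numpy(), separable_table[cols].to_numpy(),
                           rtol=0, atol=1e-12)

    def test_no_missing_values(self, separable_table):
        assert not separable_table.isna().any().any()
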