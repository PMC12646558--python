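"""Clinical statistics: rank tests, exact small-sample paths, MCID logic."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import emgrehab as er
from emgrehab.clinical import INSTRUMENTS, mann_whitney, normality_check, spearman_rho
from emgrehab.core import ConfigurationError, DataError


def brute_spearman(x, y):
    """Spearman rho via explicit average ranks and the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_monotone_identity(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_reversal(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        x, y = [1, 1, 2, 3], [2, 1, 4, 3]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(brute_spearman(x, y))

    def test_exhaustive_tie_oracle_small_windows(self):
        """rho equals the rank-formula oracle on all small integer windows."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 7))
            x = rng.integers(0, 4, n).tolist()
            y = rng.integers(0, 4, n).tolist()
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, p = spearman_rho(x, y)
            assert rho == pytest.approx(brute_spearman(x, y))
            assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0

    def test_exact_permutation_p_matches_enumeration(self):
        """For n<=8 the p-value is the exact permutation tail probability."""
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho_obs, p = spearman_rho(x, y)
        count = total = 0
        for perm in itertools.permutations(y):
            r = brute_spearman(x, list(perm))
            count += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        rho1, p1 = spearman_rho(x, y)
        rho2, p2 = spearman_rho(x, y ** 3)  # strictly monotone transform
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_vector_is_undefined(self):
        rho, p = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            spearman_rho([1, 2, 3], [1, 2, 3, 4])


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_are_central(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == pytest.approx(3 * 3 / 2)  # mn/2 under the tie convention
        assert p > 0.9

    def test_exact_p_matches_full_enumeration_3v3(self):
        x, y = [1.2, 3.4, 2.2], [2.9, 4.1, 5.0]
        u, p = mann_whitney(x, y)
        pooled = x + y
        mu = 9 / 2
        obs = abs(u - mu)
        hits = total = 0
        for comb in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in comb]
            b = [pooled[i] for i in range(6) if i not in comb]
            u_p = sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)
            hits += abs(u_p - mu) >= obs - 1e-12
            total += 1
        assert total == 20
        assert p == pytest.approx(hits / total)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestNormalityCheck:
    def test_constant_sample_flagged(self):
        w, p = normality_check([2.0] * 10)
        assert np.isnan(w) and np.isnan(p)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(DataError):
            normality_check([1.0, 2.0])

    def test_null_p_values_are_uniform(self):
        """Normal data: Shapiro-Wilk p uniform over 200 replications."""
        rng = np.random.default_rng(19)
        pvals = [normality_check(rng.standard_normal(500))[1] for _ in range(200)]
        from scipy import stats as spstats

        ks = spstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_exponential_data_rejected_often(self):
        rng = np.random.default_rng(20)
        rejections = sum(normality_check(rng.exponential(size=500))[1] < 0.05
                         for _ in range(50))
        assert rejections >= 45


class TestAggregation:
    def _table(self):
        return pd.DataFrame({
            "patient_id": ["a", "a", "b", "b"],
            "group": ["experimental"] * 4,
            "week": [0, 0, 0, 0],
            "movement": ["flexion"] * 4,
            "repetition": [1, 1, 1, 1],
            "window_idx": [0, 1, 0, 1],
            "rms_ch1": [1.0, 3.0, 5.0, 7.0],
            "rms_ch2": [2.0, 4.0, 6.0, 8.0],
        })

    def test_hand_built_mean(self):
        out = er.summarize_patient_features(self._table(), week=0)
        a = out[out.patient_id == "a"]["rms"].iloc[0]
        b = out[out.patient_id == "b"]["rms"].iloc[0]
        assert a == pytest.approx((1 + 3 + 2 + 4) / 4)  # windows then channels
        assert b == pytest.approx((5 + 7 + 6 + 8) / 4)

    def test_duplicating_windows_leaves_mean_unchanged(self):
        t = self._table()
        doubled = pd.concat([t, t], ignore_index=True)
        a = er.summarize_patient_features(t, 0)
        b = er.summarize_patient_features(doubled, 0)
        pd.testing.assert_frame_equal(a, b)

    def test_single_cell_identity(self):
        t = self._table().iloc[:1].drop(columns=["rms_ch2"])
        out = er.summarize_patient_features(t, 0)
        assert out["rms"].iloc[0] == 1.0


class TestOutcomeSummary:
    @staticmethod
    def _records(exp_pre, exp_post, ctrl_pre, ctrl_post, n=8, spread=1.0, seed=0):
        """Cohort whose group means equal the requested values exactly."""
        rng = np.random.default_rng(seed)
        rows = []
        for g, pre, post in (("experimental", exp_pre, exp_post),
                             ("control", ctrl_pre, ctrl_post)):
            noise = rng.normal(0, spread, n)
            noise -= noise.mean()  # exact group means
            for i in range(n):
                for w, mean in ((0, pre), (9, post)):
                    val = mean + noise[i]
                    rows.append({"patient_id": f"{g}{i}", "group": g, "week": w,
                                 "fma_ue": val, "arat": val, "bbt": val})
        return pd.DataFrame(rows)

    def test_reported_fma_difference_in_differences(self):
        rec = self._records(40.84, 55.92, 36.61, 42.23)
        out = er.outcome_summary(rec)
        row = out[out.instrument == "fma_ue"].iloc[0]
        assert row["diff_in_diff"] == pytest.approx(9.46, abs=1e-9)
        assert row["exceeds_mcid"] and row["mcid"] == 9.0

    def test_reported_bbt_difference_in_differences(self):
        rec = self._records(15.11, 39.50, 11.76, 15.69)
        out = er.outcome_summary(rec)
        row = out[out.instrument == "bbt"].iloc[0]
        assert row["diff_in_diff"] == pytest.approx(20.46, abs=1e-9)
        assert row["exceeds_mcid"] and row["mcid"] == 6.0

    def test_identical_trajectories_do_not_exceed(self):
        rec = self._records(30.0, 35.0, 30.0, 35.0)
        out = er.outcome_summary(rec)
        assert not out["exceeds_mcid"].any()
        assert np.allclose(out["diff_in_diff"], 0.0)

    def test_mcid_boundary_is_strict(self):
        assert er.diff_in_differences(30, 48, 30, 39) == pytest.approx(9.0)
        rec = self._records(30.0, 48.0, 30.0, 39.0)
        out = er.outcome_summary(rec)
        row = out[out.instrument == "fma_ue"].iloc[0]
        assert row["diff_in_diff"] == pytest.approx(9.0, abs=1e-9)
        assert not row["exceeds_mcid"]  # equality does not exceed
        assert row["margin"] == pytest.approx(0.0, abs=1e-9)

    def test_shift_invariance_of_diff_in_diff(self):
        rec = self._records(30.0, 40.0, 28.0, 33.0)
        shifted = rec.copy()
        for col in INSTRUMENTS:
            shifted[col] = shifted[col] + 17.3
        a = er.outcome_summary(rec)
        b = er.outcome_summary(shifted)
        assert np.allclose(a["diff_in_diff"], b["diff_in_diff"])


class TestCorrelationTable:
    def test_shuffled_scores_rarely_significant(self):
        """Clinical scores shuffled across patients: flag rate near alpha."""
        rng = np.random.default_rng(23)
        n = 40
        rates = []
        for rep in range(25):
            summ = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                                 "rms": rng.standard_normal(n)})
            clin = pd.DataFrame({
                "patient_id": [f"p{i}" for i in range(n)],
                "group": ["experimental"] * n,
                "week": [9] * n,
                "fma_ue": rng.permutation(np.arange(n)).astype(float),
                "arat": rng.permutation(np.arange(n)).astype(float),
                "bbt": rng.permutation(np.arange(n)).astype(float),
            })
            table = er.correlation_table({9: summ}, clin, [9])
            rates.append(table["significant"].mean())
        assert 0.0 <= np.mean(rates) < 0.12

    def test_too_few_patients_marked_unavailable(self):
        summ = pd.DataFrame({"patient_id": ["a", "b", "c"],
                             "rms": [1.0, 2.0, 3.0]})
        clin = pd.DataFrame({"patient_id": ["a", "b", "c"],
                             "group": ["g"] * 3, "week": [0] * 3,
                             "fma_ue": [1, 2, 3], "arat": [1, 2, 3],
                             "bbt": [1, 2, 3]})
        table = er.correlation_table({0: summ}, clin, [0])
        assert (table["strength"] == "unavailable").all()
        assert not table["significant"].any()

    def test_strength_labels(self):
        cfg = er.StatsConfig()
        assert er.strength_label(0.1, cfg) == "weak"
        assert er.strength_label(-0.45, cfg) == "moderate"
        assert er.strength_label(0.85, cfg) == "strong"
        assert er.strength_label(0.3, cfg) == "moderate"  # boundary inclusive
        assert er.strength_label(0.6, cfg) == "strong"


def test_stats_config_validation():
    with pytest.raises(ConfigurationError):
        er.StatsConfig(alpha=1.5)
    with pytest.raises(ConfigurationError):
        er.StatsConfig(weak_cutoff=0.7, strong_cutoff=0.6)
    with pytest.raises(ConfigurationError):
        er.McidThresholds(fma_ue=0.0)
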