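"""Similarity metrics, MID bins, Spearman statistics, and the six-bin
strength classification with its study-level summaries."""

import datetime as dt
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peerma import concordance as cc
from peerma.simulate import SimulationConfig, simulate_latent, simulate_wearable
from peerma.types import Construct, WearableDay

from conftest import MONDAY


class TestSimilarityScores:
    def test_identical_series(self):
        s = cc.similarity_scores([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert (s.mae, s.mse, s.rmse, s.r2) == (0.0, 0.0, 0.0, 1.0)

    def test_hand_evaluated_case(self):
        s = cc.similarity_scores([0, 0.5, 1], [0.1, 0.5, 0.9])
        assert s.mae == pytest.approx(0.0667, abs=1e-4)
        assert s.mse == pytest.approx(0.00667, abs=1e-5)
        assert s.rmse == pytest.approx(0.0816, abs=1e-4)
        assert s.r2 == pytest.approx(0.96)

    def test_mean_predictor_gives_zero_r2(self):
        patient = [0.2, 0.4, 0.9]
        mean = sum(patient) / 3
        s = cc.similarity_scores(patient, [mean] * 3)
        assert s.r2 == pytest.approx(0.0)

    def test_constant_patient_series_undefined_r2(self):
        with pytest.raises(cc.ConstantSeriesError):
            cc.similarity_scores([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])
        # error metrics remain available through the metrics helper
        mae, mse, rmse = cc.error_metrics([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])
        assert mae == pytest.approx(0.2 / 3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=2, max_size=20
        ).filter(lambda v: max(v) - min(v) > 1e-3),
    )
    def test_self_similarity_and_rmse_consistency(self, values):
        s = cc.similarity_scores(values, values)
        assert (s.mae, s.mse, s.rmse, s.r2) == (0.0, 0.0, 0.0, 1.0)
        shifted = [min(1.0, v + 0.1) for v in values]
        t = cc.similarity_scores(values, shifted)
        assert t.rmse**2 == pytest.approx(t.mse, abs=1e-12)
        assert t.mae <= t.rmse + 1e-12


class TestMeanDifferenceBin:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (0.64, 0.64, "<=5%"),
            (0.82, 0.72, "<=10%"),  # d = 0.10 exactly: upper-inclusive
            (0.77, 0.39, ">15%"),
            (0.60, 0.48, "<=15%"),
            (0.05, 0.0, "<=5%"),
            (0.151, 0.0, ">15%"),
        ],
    )
    def test_binning(self, a, b, expected):
        assert cc.mean_difference_bin(a, b) == expected

    def test_symmetric(self):
        assert cc.mean_difference_bin(0.3, 0.42) == cc.mean_difference_bin(0.42, 0.3)

    def test_rejects_out_of_range_means(self):
        with pytest.raises(ValueError):
            cc.mean_difference_bin(1.2, 0.5)


def brute_force_ranks(values):
    out = []
    for x in values:
        less = sum(1 for v in values if v < x)
        equal = sum(1 for v in values if v == x)
        out.append(less + (equal + 1) / 2)
    return out


def brute_force_spearman(x, y):
    rx, ry = brute_force_ranks(x), brute_force_ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_force_permutation_p(x, y):
    observed = abs(brute_force_spearman(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(brute_force_spearman(x, list(perm))) >= observed - 1e-12:
            hits += 1
    return hits / total


class TestSpearman:
    def test_monotone_identity(self):
        rs, _ = cc.spearman_rs([1, 2, 3, 4], [10, 20, 30, 40])
        assert rs == pytest.approx(1.0)

    def test_reversed_order(self):
        rs, _ = cc.spearman_rs([1, 2, 3, 4], [4, 3, 2, 1])
        assert rs == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(cc.ConstantSeriesError):
            cc.spearman_rs([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(cc.InsufficientDataError):
            cc.spearman_rs([1, 2], [2, 1])

    @pytest.mark.parametrize("seed", range(12))
    def test_small_n_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        x = rng.integers(0, 5, n).astype(float).tolist()
        y = rng.integers(0, 5, n).astype(float).tolist()
        if len(set(x)) < 2 or len(set(y)) < 2:
            x[0], y[0] = x[0] + 1, y[0] + 1
        rs, p = cc.spearman_rs(x, y)
        assert rs == pytest.approx(brute_force_spearman(x, y), abs=1e-12)
        assert p == pytest.approx(brute_force_permutation_p(x, y), abs=0.02)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.8, size=30)
        from scipy import stats

        rs, p = cc.spearman_rs(x, y)
        ref = stats.spearmanr(x, y)
        assert (rs, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "rs, expected",
        [
            (0.96, cc.StrengthClass.HIGHLY_POSITIVE),
            (0.67, cc.StrengthClass.HIGHLY_POSITIVE),
            (0.66, cc.StrengthClass.MODERATELY_POSITIVE),
            (0.335, cc.StrengthClass.MODERATELY_POSITIVE),  # rounds half-up
            (0.33, cc.StrengthClass.WEAKLY_POSITIVE),
            (0.0, cc.StrengthClass.WEAKLY_POSITIVE),
            (-0.005, cc.StrengthClass.WEAKLY_NEGATIVE),
            (-0.33, cc.StrengthClass.WEAKLY_NEGATIVE),
            (-0.50, cc.StrengthClass.MODERATELY_NEGATIVE),
            (-0.66, cc.StrengthClass.MODERATELY_NEGATIVE),
            (-0.67, cc.StrengthClass.HIGHLY_NEGATIVE),
            (-1.0, cc.StrengthClass.HIGHLY_NEGATIVE),
            (1.0, cc.StrengthClass.HIGHLY_POSITIVE),
        ],
    )
    def test_bin_assignment(self, rs, expected):
        assert cc.classify_strength(rs) is expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cc.classify_strength(1.01)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(rs=st.floats(-1, 1, allow_nan=False))
    def test_partitions_the_interval(self, rs):
        # every value maps to exactly one class, with the right sign side
        cls = cc.classify_strength(rs)
        assert isinstance(cls, cc.StrengthClass)
        if rs >= 0.005:
            assert "positive" in cls.value
        elif rs < -0.005:
            assert "negative" in cls.value


class TestClassificationSummary:
    def test_single_moderate_correlation(self):
        frame = pd.DataFrame({"construct": ["hope"], "rs": [0.5]})
        summary = cc.classification_summary(frame)
        row = summary.set_index("strength")
        assert row.loc["moderately_positive", "hope_n"] == 1
        assert row.loc["moderately_positive", "total_pct"] == 100
        assert row.drop("moderately_positive")["total_n"].sum() == 0

    def test_dyad_correlations_fatigue_column(self, fixtures):
        summary = cc.classification_summary(
            fixtures.table10_dyad_correlations
        ).set_index("strength")
        assert summary.loc["highly_positive", "fatigue_n"] == 4
        assert summary.loc["highly_positive", "fatigue_pct"] == 57

    def test_steps_correlations_highly_negative(self, fixtures):
        summary = cc.classification_summary(
            fixtures.table8_steps_correlations
        ).set_index("strength")
        assert summary.loc["highly_negative", "total_n"] == 10
        assert summary.loc["highly_negative", "total_pct"] == 40


class TestEmaWearableCorrelation:
    def _wearable(self, steps):
        return [
            WearableDay(
                dyad_id="1", date=MONDAY + dt.timedelta(days=i), steps=s
            )
            for i, s in enumerate(steps)
        ]

    def _assessments(self, values):
        return {
            Construct.HOPE: {
                MONDAY + dt.timedelta(days=i): v for i, v in enumerate(values)
            }
        }

    def test_strictly_increasing_gives_unit_correlation(self):
        result = cc.ema_wearable_correlation(
            self._assessments([0.1, 0.3, 0.5, 0.8]),
            self._wearable([1000, 2000, 3000, 4000]),
        )
        rs, _ = result[Construct.HOPE]
        assert rs == pytest.approx(1.0)

    def test_fewer_than_three_common_days(self):
        with pytest.raises(cc.InsufficientDataError):
            cc.ema_wearable_correlation(
                self._assessments([0.1, 0.5]), self._wearable([1000, 2000])
            )

    def test_negative_fatigue_coupling_recovered(self):
        # simulated patient with a negative fatigue->steps weight:
        # fatigue/steps correlation negative in >= 4 of 5 seeds
        negatives = 0
        for seed in range(5):
            config = SimulationConfig(n_days=120)
            latent = {
                c: simulate_latent(config, c, seed=200 + seed * 11 + i)
                for i, c in enumerate(Construct)
            }
            wearable = simulate_wearable(latent, config, seed=seed)
            observed = {
                Construct.FATIGUE: {
                    MONDAY + dt.timedelta(days=d): latent[Construct.FATIGUE].values[d]
                    for d in range(0, 120, 3)
                }
            }
            wearable = [
                WearableDay(
                    dyad_id="1",
                    date=MONDAY + dt.timedelta(days=i),
                    steps=w.steps,
                )
                for i, w in enumerate(wearable)
            ]
            rs, _ = cc.ema_wearable_correlation(observed, wearable)[
                Construct.FATIGUE
            ]
            negatives += rs < 0
        assert negatives >= 4
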