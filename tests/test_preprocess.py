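"""Dedup / alignment / normalization / ridge-polynomial imputation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peerma.preprocess import (
    AlignmentError,
    ImputationError,
    align_streams,
    build_dyad_streams,
    deduplicate_daily,
    impute_daily_curve,
    fit_daily_curve,
    normalize_per_person,
)
from peerma.types import Construct, Role

from conftest import MONDAY, record


def ts(day, hour=10, minute=0):
    return dt.datetime(2019, 9, 2 + day, hour, minute)


class TestDeduplicateDaily:
    def test_complete_beats_incomplete(self):
        pair = [record(timestamp=ts(0, 9), complete=True, value=0.4),
                record(timestamp=ts(0, 11), complete=False)]
        (kept,) = deduplicate_daily(pair)
        assert kept.complete and kept.value_raw == 0.4

    def test_newest_of_two_complete_kept(self):
        t1, t2 = ts(0, 9), ts(0, 12)
        pair = [record(timestamp=t1, value=0.1), record(timestamp=t2, value=0.9)]
        (kept,) = deduplicate_daily(pair)
        assert kept.timestamp == t2

    def test_mixed_triple_keeps_newest_complete(self):
        triple = [
            record(timestamp=ts(0, 8), complete=False),
            record(timestamp=ts(0, 10), value=0.3),
            record(timestamp=ts(0, 12), value=0.7),
        ]
        (kept,) = deduplicate_daily(triple)
        assert kept.timestamp == ts(0, 12) and kept.value_raw == 0.7

    def test_different_constructs_untouched(self):
        records = [
            record(construct=Construct.HOPE, timestamp=ts(0)),
            record(construct=Construct.PAIN, timestamp=ts(0)),
        ]
        assert len(deduplicate_daily(records)) == 2

    def test_idempotent_and_unique_per_day(self):
        records = [
            record(timestamp=ts(d, h), value=0.1 * h % 1, complete=h != 9)
            for d in range(3)
            for h in (8, 9, 12)
        ]
        once = deduplicate_daily(records)
        assert deduplicate_daily(once) == once
        keys = [(r.construct, r.date) for r in once]
        assert len(keys) == len(set(keys))


class TestAlignStreams:
    def test_patient_start_and_earliest_end(self):
        # patient Jan 1-30, peer Dec 28-Jan 25 -> range Jan 1-25
        patient = [
            record(timestamp=dt.datetime(2020, 1, d, 10)) for d in (1, 15, 30)
        ]
        peer = [
            record(timestamp=t, role=Role.SUPPORT_PERSON)
            for t in (
                dt.datetime(2019, 12, 28, 10),
                dt.datetime(2020, 1, 10, 10),
                dt.datetime(2020, 1, 25, 10),
            )
        ]
        (start, end), p_trim, s_trim = align_streams(patient, peer)
        assert (start, end) == (dt.date(2020, 1, 1), dt.date(2020, 1, 25))
        assert all(start <= r.date <= end for r in p_trim + s_trim)
        assert len(s_trim) == 2  # Dec 28 trimmed away

    def test_identical_ranges_unchanged(self):
        patient = [record(timestamp=ts(d)) for d in range(3)]
        peer = [record(timestamp=ts(d), role=Role.SUPPORT_PERSON) for d in range(3)]
        (start, end), p_trim, s_trim = align_streams(patient, peer)
        assert (p_trim, s_trim) == (patient, peer)

    def test_no_overlap_error(self):
        patient = [record(timestamp=dt.datetime(2020, 2, 1, 10))]
        peer = [
            record(
                timestamp=dt.datetime(2020, 1, 1, 10), role=Role.SUPPORT_PERSON
            )
        ]
        with pytest.raises(AlignmentError, match="no overlap"):
            align_streams(patient, peer)

    def test_empty_stream_names_role(self):
        with pytest.raises(AlignmentError, match="support-person"):
            align_streams([record()], [])
        with pytest.raises(AlignmentError, match="patient"):
            align_streams([], [record(role=Role.SUPPORT_PERSON)])

    def test_realign_never_extends_the_range(self):
        patient = [record(timestamp=ts(d)) for d in (0, 5, 20)]
        peer = [
            record(timestamp=ts(d), role=Role.SUPPORT_PERSON) for d in (2, 10)
        ]
        rng1, p1, s1 = align_streams(patient, peer)
        rng2, _, _ = align_streams(p1, s1)
        assert rng1[0] <= rng2[0] and rng2[1] <= rng1[1]

    def test_fixed_point_when_boundary_reports_survive(self):
        # both roles report on the end date: one pass already converges
        patient = [record(timestamp=ts(d)) for d in (0, 5, 10)]
        peer = [
            record(timestamp=ts(d), role=Role.SUPPORT_PERSON) for d in (2, 10, 15)
        ]
        rng1, p1, s1 = align_streams(patient, peer)
        rng2, p2, s2 = align_streams(p1, s1)
        assert rng1 == rng2 and (p1, s1) == (p2, s2)


class TestNormalize:
    def normalize_values(self, raws, scope="per_construct"):
        records = [
            record(timestamp=ts(i), value=v) for i, v in enumerate(raws)
        ]
        return [r.value_norm for r in normalize_per_person(records, scope)]

    def test_min_max_forced(self):
        assert self.normalize_values([2, 5, 8]) == pytest.approx([0, 0.5, 1])

    def test_hand_evaluated_case(self):
        assert self.normalize_values([0.1, 0.4, 0.55, 1.0]) == pytest.approx(
            [0, 1 / 3, 0.5, 1]
        )

    def test_degenerate_group_maps_to_center(self):
        assert self.normalize_values([0.4, 0.4, 0.4]) == [0.5, 0.5, 0.5]

    def test_scope_pools_across_constructs(self):
        records = [
            record(construct=Construct.HOPE, timestamp=ts(0), value=0.0),
            record(construct=Construct.PAIN, timestamp=ts(1), value=1.0),
            record(construct=Construct.PAIN, timestamp=ts(2), value=0.5),
        ]
        pooled = normalize_per_person(records, "all_constructs")
        assert [r.value_norm for r in pooled] == pytest.approx([0.0, 1.0, 0.5])
        per = normalize_per_person(records, "per_construct")
        assert [r.value_norm for r in per] == pytest.approx([0.5, 1.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        raws=st.lists(
            st.floats(0, 10, allow_nan=False), min_size=3, max_size=12
        ).filter(lambda v: max(v) - min(v) > 1e-2),
        scale=st.floats(0.5, 20),
        shift=st.floats(-5, 5),
    )
    def test_invariant_to_positive_affine_transform(self, raws, scale, shift):
        direct = self.normalize_values(raws)
        transformed = self.normalize_values([scale * v + shift for v in raws])
        assert direct == pytest.approx(transformed, abs=1e-9)


def ridge_oracle(t, y, penalty):
    """Closed-form penalized normal equations (XtX + penalty*D) b = Xty with
    X = [1, t, t^2] and the intercept unpenalized."""
    X = np.column_stack([np.ones_like(t), t, t**2])
    D = np.diag([0.0, 1.0, 1.0])
    return np.linalg.solve(X.T @ X + penalty * D, X.T @ y)


class TestImputeDailyCurve:
    RANGE = (MONDAY, MONDAY + dt.timedelta(days=9))

    def observed(self, day_values):
        return {MONDAY + dt.timedelta(days=d): v for d, v in day_values.items()}

    def test_exact_parabola_interpolated_with_zero_penalty(self):
        # y = 0.1 + 0.5 t + 0.3 t^2 on the rescaled grid
        f = lambda t: 0.1 + 0.5 * t + 0.3 * t**2
        observed = self.observed({0: f(0.0), 4: f(4 / 9), 9: f(1.0)})
        series = impute_daily_curve(observed, self.RANGE, penalty=0.0)
        expected = [f(d / 9) for d in range(10)]
        assert series == pytest.approx(expected, abs=1e-8)

    def test_constant_observations_give_constant_curve(self):
        observed = self.observed({0: 0.6, 3: 0.6, 8: 0.6})
        series = impute_daily_curve(observed, self.RANGE, penalty=5.0)
        assert series == pytest.approx([0.6] * 10, abs=1e-8)

    def test_matches_closed_form_penalized_solution(self):
        observed = self.observed({0: 0.2, 2: 0.8, 5: 0.4, 7: 0.9, 9: 0.3})
        penalty = 1.0
        days = sorted((d - MONDAY).days for d in observed)
        t = np.array(days) / 9
        y = np.array([observed[MONDAY + dt.timedelta(days=d)] for d in days])
        beta = ridge_oracle(t, y, penalty)
        fitted = fit_daily_curve(observed, self.RANGE, penalty)
        t_grid = np.arange(10) / 9
        expected = beta[0] + beta[1] * t_grid + beta[2] * t_grid**2
        assert fitted == pytest.approx(expected, abs=1e-8)

    def test_observed_days_kept_verbatim(self):
        observed = self.observed({0: 0.2, 5: 0.95, 9: 0.1})
        series = impute_daily_curve(observed, self.RANGE, penalty=1.0)
        for date, value in observed.items():
            assert series[(date - MONDAY).days] == value

    def test_large_penalty_flattens_to_mean(self):
        observed = self.observed({0: 0.2, 3: 0.8, 6: 0.5, 9: 0.7})
        series = fit_daily_curve(observed, self.RANGE, penalty=1e9)
        assert np.ptp(series) < 1e-6
        assert series[0] == pytest.approx(np.mean(list(observed.values())), abs=1e-5)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ImputationError):
            impute_daily_curve(self.observed({0: 0.5, 9: 0.6}), self.RANGE)

    def test_values_clipped_to_unit_interval(self):
        observed = self.observed({0: 0.0, 1: 1.0, 2: 0.0, 9: 1.0})
        series = impute_daily_curve(observed, self.RANGE, penalty=0.0)
        assert all(0.0 <= v <= 1.0 for v in series)


class TestBuildDyadStreams:
    def test_noiseless_dyad_streams_cover_grid(self, noiseless_dyad):
        streams = build_dyad_streams(
            noiseless_dyad.patient_records, noiseless_dyad.peer_records
        )
        n_days = (streams.date_range[1] - streams.date_range[0]).days + 1
        for construct in Construct:
            assert len(streams.patient_daily[construct]) == n_days
            assert all(0 <= v <= 1 for v in streams.patient_daily[construct])

    def test_sparse_construct_falls_back_to_constant(self, caplog):
        patient = [record(timestamp=ts(d), value=0.3 + 0.05 * d) for d in range(6)]
        # pain observed only twice: constant-mean fallback, not a crash
        patient += [
            record(construct=Construct.PAIN, timestamp=ts(0), value=0.2),
            record(construct=Construct.PAIN, timestamp=ts(5), value=0.4),
        ]
        peer = [
            record(timestamp=ts(d), role=Role.SUPPORT_PERSON, value=0.5)
            for d in range(6)
        ]
        streams = build_dyad_streams(patient, peer)
        pain = streams.patient_daily[Construct.PAIN]
        assert pain[1] == pytest.approx(0.5)  # min-max normalized mean of {0,1}
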