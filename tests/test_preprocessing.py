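import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catfda.io import EpochSeries
from catfda.preprocessing import (
    WEEKDAY,
    WEEKEND,
    DailyCurve,
    PreprocessingError,
    bin_five_minutes,
    build_profile,
    cohort_summary,
    group_mean_profiles,
    log_transform,
    profile_from_series,
    select_baseline_days,
    split_daytype,
)
from catfda.synthetic import GeneratorConfig, generate_cohort


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        assert log_transform(np.array([0])) == pytest.approx(0.0)

    def test_inverse_identity(self):
        assert log_transform(np.array([np.e - 1]))[0] == pytest.approx(1.0)

    def test_direct_evaluation(self):
        np.testing.assert_allclose(
            log_transform(np.array([0, 99])), [0.0, np.log(100.0)]
        )

    def test_negative_rejected(self):
        with pytest.raises(PreprocessingError):
            log_transform(np.array([-1.0]))


class TestBinFiveMinutes:
    def test_constant_preserved(self):
        np.testing.assert_allclose(bin_five_minutes(np.full(1440, 3.7)), 3.7)

    def test_minute_index_means(self):
        out = bin_five_minutes(np.arange(1440, dtype=float))
        np.testing.assert_allclose(out, 5 * np.arange(288) + 2)

    def test_matches_brute_force_loop(self, rng):
        values = rng.normal(size=1440)
        expected = np.array([values[5 * j: 5 * j + 5].mean() for j in range(288)])
        np.testing.assert_allclose(bin_five_minutes(values), expected)

    def test_wrong_length_rejected(self):
        with pytest.raises(PreprocessingError):
            bin_five_minutes(np.zeros(288))

    def test_transform_then_bin_order_matters(self, rng):
        """Guards against silently reordering the pipeline: on non-constant
        counts, bin(ln(1+x)) != ln(1+bin(x)) by Jensen's inequality."""
        counts = rng.integers(0, 200, size=1440).astype(float)
        a = bin_five_minutes(log_transform(counts))
        b = log_transform(bin_five_minutes(counts))
        assert np.abs(a - b).max() > 1e-6
        assert np.all(a <= b + 1e-12)  # concavity direction


class TestDaytypeAndBaseline:
    def test_saturday_is_weekend(self):
        assert split_daytype(dt.date(2015, 6, 6)) == WEEKEND

    def test_wednesday_is_weekday(self):
        assert split_daytype(dt.date(2015, 6, 3)) == WEEKDAY

    def test_seven_consecutive_days_have_two_weekend_labels(self):
        start = dt.date(2015, 6, 1)
        labels = [split_daytype(start + dt.timedelta(days=d)) for d in range(7)]
        assert labels.count(WEEKEND) == 2

    @staticmethod
    def _days(n, start=dt.date(2015, 6, 1)):
        return [
            EpochSeries("c1", start + dt.timedelta(days=d), np.zeros(1440, dtype=int))
            for d in range(n)
        ]

    def test_fifteen_days_yields_last_seven_usable(self):
        days = self._days(15)
        chosen = select_baseline_days(days)
        # first and last deleted -> 13 usable; the last 7 of those
        assert [s.date for s in chosen] == [d.date for d in days[7:14]]

    def test_exactly_nine_days_yields_middle_seven(self):
        days = self._days(9)
        chosen = select_baseline_days(days)
        assert [s.date for s in chosen] == [d.date for d in days[1:8]]

    def test_eight_days_insufficient(self):
        with pytest.raises(PreprocessingError, match="c1"):
            select_baseline_days(self._days(8))


def _curves(wd_values, we_values):
    return [DailyCurve(v, WEEKDAY) for v in wd_values] + [
        DailyCurve(v, WEEKEND) for v in we_values
    ]


class TestBuildProfile:
    def test_constant_profile(self):
        c = 2.5
        prof = build_profile(_curves([np.full(288, c)] * 5, [np.full(288, c)] * 2), "c1")
        assert prof.ave == pytest.approx(c)
        np.testing.assert_allclose(prof.I_weekday, 0.0, atol=1e-14)
        np.testing.assert_allclose(prof.I_weekend, 0.0, atol=1e-14)

    def test_two_level_closed_form(self):
        a, b = 2.0, 3.4
        prof = build_profile(_curves([np.full(288, a)] * 5, [np.full(288, b)] * 2), "c1")
        ave = (5 * a + 2 * b) / 7
        assert prof.ave == pytest.approx(ave)
        np.testing.assert_allclose(prof.I_weekday, a - ave)
        np.testing.assert_allclose(prof.I_weekend, b - ave)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_weighted_intensity_mean_zero_identity(self, seed):
        """(5 mean_t I_wd + 2 mean_t I_we) / 7 == 0 on every complete profile."""
        r = np.random.default_rng(seed)
        prof = build_profile(
            _curves(list(r.normal(3, 1, (5, 288))), list(r.normal(3, 1, (2, 288)))),
            "c1",
        )
        resid = (5 * prof.I_weekday.mean() + 2 * prof.I_weekend.mean()) / 7
        assert abs(resid) < 1e-12

    def test_wrong_daytype_counts_rejected(self):
        with pytest.raises(PreprocessingError, match="5 weekday"):
            build_profile(_curves([np.zeros(288)] * 4, [np.zeros(288)] * 3), "c1")


class TestGroupProfiles:
    def test_single_subject_is_its_own_mean(self, small_profiles):
        profiles, _ = small_profiles
        cid, prof = next(iter(profiles.items()))
        gm = group_mean_profiles([prof], {cid: "G"})
        np.testing.assert_allclose(gm[("G", WEEKDAY)]["activity"], prof.Y_weekday)

    def test_pointwise_linearity(self, small_profiles):
        profiles, _ = small_profiles
        (c1, p1), (c2, p2) = list(profiles.items())[:2]
        gm = group_mean_profiles([p1, p2], {c1: "G", c2: "G"})
        np.testing.assert_allclose(
            gm[("G", WEEKEND)]["activity"], (p1.Y_weekend + p2.Y_weekend) / 2
        )

    def test_empty_group_rejected(self, small_profiles):
        profiles, _ = small_profiles
        cid, prof = next(iter(profiles.items()))
        with pytest.raises(PreprocessingError):
            group_mean_profiles([prof], {cid: "G", "ghost": "H"})

    def test_noise_free_cohort_recovers_template(self):
        """With no noise and no subject effects the group mean equals the
        planted template up to count rounding on the log scale."""
        config = GeneratorConfig(
            seed=7, n_per_group=(("Normal", 3), ("DJD", 3)),
            noise_sd=0.0, eigen_spec=((1, 0.0),), beta_spec={},
        )
        series, covariates, truth = generate_cohort(config)
        by_cat = {}
        for s in series:
            by_cat.setdefault(s.cat_id, []).append(s)
        profiles = [profile_from_series(d) for d in by_cat.values()]
        groups = dict(zip(covariates["cat_id"], covariates["group"]))
        gm = group_mean_profiles(profiles, groups)
        for g in ("Normal", "DJD"):
            template = truth.templates[(g, WEEKDAY)]
            err = np.abs(gm[(g, WEEKDAY)]["activity"] - template)
            counts = np.expm1(template)
            assert err[counts >= 25].max() < 0.02
            assert err.max() < 0.1  # analytic rounding bound at lower counts


class TestCohortSummary:
    def test_constant_subjects(self):
        means = {f"c{i}": 4.2 for i in range(5)}
        df = cohort_summary(means, {c: "G" for c in means})
        row = df.iloc[0]
        for col in ("minimum", "q1", "median", "mean", "q3", "maximum"):
            assert row[col] == pytest.approx(4.2)

    def test_small_exact_case(self):
        means = {f"c{i}": float(i + 1) for i in range(5)}  # 1..5
        row = cohort_summary(means, {c: "G" for c in means}).iloc[0]
        assert row["median"] == pytest.approx(3.0)
        assert row["mean"] == pytest.approx(3.0)

    def test_matches_independent_type7_quantiles(self, rng):
        """Cross-check against the stdlib's inclusive (type-7) quantiles."""
        import statistics

        vals = rng.gamma(3, 10, size=17)
        means = {f"c{i}": float(v) for i, v in enumerate(vals)}
        row = cohort_summary(means, {c: "G" for c in means}).iloc[0]
        q1, q2, q3 = statistics.quantiles(vals, n=4, method="inclusive")
        assert row["q1"] == pytest.approx(q1)
        assert row["median"] == pytest.approx(q2)
        assert row["q3"] == pytest.approx(q3)
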