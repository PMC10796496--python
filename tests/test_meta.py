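"""Subgroup meta-analysis: pooling models, heterogeneity, Egger test."""

import numpy as np
import pytest

from htestrat.meta import (StudyRow, egger_test, forest_data,
                           iv_fixed_smd, make_studies,
                           make_continuous_studies, mh_fixed_rd, reml_random,
                           reml_tau2)


class TestMakeStudies:
    def test_fixture_drops_empty_arm_stratum(self, grouped):
        studies = make_studies(grouped, "any_ht")
        assert len(studies) == 4
        assert sum(s.n1 + s.n0 for s in studies) == 236
        assert [s.label for s in studies] == ["0", "1", "2", "3"]

    def test_effects_are_hand_computed_risk_differences(self, grouped):
        studies = make_studies(grouped, "any_ht")
        expect = [(2 / 34 - 5 / 67), (6 / 34 - 11 / 37),
                  (4 / 17 - 13 / 30), (3 / 6 - 7 / 11)]
        got = [s.effect for s in studies]
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_empty_arm_error_when_not_dropped(self, grouped):
        with pytest.raises(ValueError):
            make_studies(grouped, "any_ht", drop_empty_arm=False)


class TestMantelHaenszel:
    def test_identical_risks_pool_to_zero(self):
        studies = [StudyRow("a", 50, 50, 0.0, 0.004, e1=10, e0=10),
                   StudyRow("b", 30, 30, 0.0, 0.008, e1=3, e0=3)]
        res = mh_fixed_rd(studies)
        assert res.pooled == pytest.approx(0.0, abs=1e-12)

    def test_single_study_is_its_own_pool(self):
        s = StudyRow("a", 40, 60, e1=8, e0=6, effect=8 / 40 - 6 / 60,
                     variance=0.01)
        res = mh_fixed_rd([s])
        assert res.pooled == pytest.approx(s.effect, abs=1e-12)

    def test_fixture_pool_matches_hand_weights(self, grouped):
        studies = make_studies(grouped, "any_ht")
        w = np.array([s.n1 * s.n0 / (s.n1 + s.n0) for s in studies])
        rd = np.array([s.effect for s in studies])
        res = mh_fixed_rd(studies)
        assert res.pooled == pytest.approx(float(np.sum(w * rd) / w.sum()),
                                           abs=1e-12)

    def test_order_invariance(self, grouped):
        studies = make_studies(grouped, "sht")
        a = mh_fixed_rd(studies)
        b = mh_fixed_rd(studies[::-1])
        assert a.pooled == pytest.approx(b.pooled, abs=1e-12)


class TestHedges:
    def test_equal_means_zero(self):
        rows = make_continuous_studies(
            _cont_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "y")
        assert rows[0].effect == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_formula(self):
        # n1 = n0 = 2, mean difference 1, pooled SD 1/sqrt(2):
        # df = 2, correction J = 1 - 3/(4*2 - 1) = 1 - 3/7
        rows = make_continuous_studies(
            _cont_frame([0.5, 1.5], [-0.5, 0.5]), "y")
        g = rows[0].effect
        assert g == pytest.approx((1 - 3 / 7) * np.sqrt(2), abs=1e-12)

    def test_pooled_between_extremes(self):
        rows = [StudyRow("a", 20, 20, effect=0.2, variance=0.05,
                         kind="continuous"),
                StudyRow("b", 20, 20, effect=0.8, variance=0.08,
                         kind="continuous")]
        res = iv_fixed_smd(rows)
        assert 0.2 <= res.pooled <= 0.8


class TestReml:
    def test_published_heterogeneity_on_fixture(self, grouped):
        studies = make_studies(grouped, "any_ht")
        res = reml_random(studies)
        assert res.i2 == pytest.approx(10.9, abs=0.5)
        assert res.h2 == pytest.approx(1.12, abs=0.01)

    def test_symptomatic_ht_heterogeneity_moderate(self, grouped):
        res = reml_random(make_studies(grouped, "sht"))
        assert res.i2 == pytest.approx(35.8, abs=0.5)
        assert res.h2 == pytest.approx(1.56, abs=0.01)

    def test_identical_effects_zero_tau2(self):
        studies = [StudyRow(str(i), 50, 50, effect=0.1, variance=0.01)
                   for i in range(4)]
        res = reml_random(studies)
        assert res.tau2 == 0.0
        assert res.i2 == 0.0
        assert res.h2 == pytest.approx(1.0)
        # with tau2 = 0 the pooled estimate equals fixed inverse-variance
        assert res.pooled == pytest.approx(0.1, abs=1e-12)

    def test_tau2_maximizes_restricted_likelihood(self, rng):
        y = rng.normal(0.3, 0.25, size=8)
        v = rng.uniform(0.01, 0.05, size=8)
        tau2 = reml_tau2(y, v)

        def restricted_ll(t2):
            w = 1.0 / (v + t2)
            mu = np.sum(w * y) / np.sum(w)
            return (0.5 * np.sum(np.log(w)) - 0.5 * np.log(np.sum(w))
                    - 0.5 * np.sum(w * (y - mu) ** 2))

        grid = np.linspace(0, 0.5, 2001)
        best = grid[np.argmax([restricted_ll(t) for t in grid])]
        assert tau2 == pytest.approx(best, abs=5e-4)

    def test_i2_h2_identity(self, grouped):
        for outcome in ("sht", "any_ht", "ffo"):
            res = reml_random(make_studies(grouped, outcome))
            assert res.i2 == pytest.approx(100 * (1 - 1 / res.h2), abs=1e-9)
            assert res.h2 >= 1.0
            assert 0 <= res.i2 < 100


class TestEgger:
    def test_fixture_shows_no_small_study_effects(self, grouped):
        for outcome in ("sht", "any_ht", "ffo"):
            with pytest.warns(UserWarning):
                _, p = egger_test(make_studies(grouped, outcome))
            assert p > 0.05

    def test_symmetric_funnel_rejection_rate(self):
        rejections = 0
        reps = 120
        for i in range(reps):
            rng = np.random.default_rng(i)
            v = rng.uniform(0.01, 0.2, 20)
            y = rng.normal(0.2, np.sqrt(v))
            studies = [StudyRow(str(j), 50, 50, effect=y[j], variance=v[j])
                       for j in range(20)]
            _, p = egger_test(studies)
            rejections += p < 0.05
        # alpha=0.05 over 120 reps: mean 6, 3 MC SE ~ 7.2
        assert rejections <= 14

    def test_two_studies_insufficient(self):
        studies = [StudyRow("a", 10, 10, effect=0.1, variance=0.02),
                   StudyRow("b", 10, 10, effect=0.3, variance=0.05)]
        with pytest.raises(ValueError):
            egger_test(studies)


class TestForest:
    def test_weights_sum_to_hundred(self, grouped):
        studies = make_studies(grouped, "any_ht")
        res = reml_random(studies)
        table = forest_data(res, studies)
        assert table.loc[~table.pooled, "weight_pct"].sum() == \
            pytest.approx(100.0, abs=1e-9)

    def test_single_study_full_weight(self):
        s = StudyRow("a", 40, 60, e1=8, e0=6, effect=0.1, variance=0.01)
        table = forest_data(mh_fixed_rd([s]), [s])
        assert table.loc[~table.pooled, "weight_pct"].iloc[0] == \
            pytest.approx(100.0)

    def test_random_weights_proportional_to_inverse_variance(self, grouped):
        studies = make_studies(grouped, "any_ht")
        res = reml_random(studies)
        table = forest_data(res, studies)
        w = 1.0 / (np.array([s.variance for s in studies]) + res.tau2)
        np.testing.assert_allclose(
            table.loc[~table.pooled, "weight_pct"].to_numpy(),
            100 * w / w.sum(), atol=1e-9)


def _cont_frame(y1, y0):
    import pandas as pd
    return pd.DataFrame({
        "hti": [0] * (len(y1) + len(y0)),
        "arm": [1] * len(y1) + [0] * len(y0),
        "y": list(y1) + list(y0),
    })
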