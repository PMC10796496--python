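"""Postestimation battery: diagnostics, pseudo R2, AUC, Romano-Wolf."""

import numpy as np
import pytest
from scipy import special, stats

from htestrat.logit import fit_logit
from htestrat.selection import (PostestimationReport, box_tidwell_test,
                                compare_auc, hosmer_lemeshow, info_criteria,
                                link_test, lr_test, pseudo_r2,
                                romano_wolf_adjust, roc_auc, select_model,
                                variance_inflation)


class TestLinkTest:
    def test_published_value_on_fixture(self, sht_fit):
        assert link_test(sht_fit) == pytest.approx(0.127, abs=1e-3)

    def test_null_calibration_small(self, rng):
        """Well-specified logit: squared-term p roughly uniform."""
        rejections = 0
        reps = 60
        for _ in range(reps):
            x = rng.normal(size=3000)
            y = (rng.random(3000) < special.expit(-0.5 + x)).astype(float)
            f = fit_logit(y, x[:, None])
            rejections += link_test(f) < 0.05
        # binomial(60, 0.05): mean 3, sd 1.7
        assert rejections <= 9

    def test_power_against_quadratic(self, rng):
        x = rng.normal(size=20000)
        y = (rng.random(20000)
             < special.expit(-0.5 + x + 0.8 * x ** 2)).astype(float)
        f = fit_logit(y, x[:, None])
        assert link_test(f) < 1e-3


class TestBoxTidwell:
    def test_linear_in_logit_usually_passes(self, rng):
        passes = 0
        reps = 40
        for _ in range(reps):
            x = rng.integers(0, 5, 2500).astype(float)
            y = (rng.random(2500) < special.expit(-2 + 0.8 * x)).astype(float)
            f = fit_logit(y, x[:, None])
            passes += box_tidwell_test(f, ["x0"])["p"]["x0"] > 0.05
        assert passes >= 0.8 * reps

    def test_power_against_log_relationship(self, rng):
        x = rng.uniform(0.5, 20, 20000)
        y = (rng.random(20000) < special.expit(-2 + 2 * np.log(x)))
        f = fit_logit(y.astype(float), x[:, None])
        assert box_tidwell_test(f, ["x0"])["p"]["x0"] < 0.01

    def test_shift_reported_for_zero_scores(self, sht_fit):
        out = box_tidwell_test(sht_fit, ["hti"], shift=1.0)
        assert out["shift"] == 1.0
        assert 0.0 <= out["p"]["hti"] <= 1.0


class TestHosmerLemeshow:
    def test_fixture_collapses_to_published_df(self, sht_fit):
        chi2, df, p = hosmer_lemeshow(sht_fit, groups=10)
        assert df == 6
        assert chi2 == pytest.approx(4.17, abs=0.01)
        assert p == pytest.approx(0.654, abs=1e-3)

    def test_calibrated_chi2_near_df(self, rng):
        chis, dfs = [], []
        for _ in range(30):
            x = rng.normal(size=4000)
            y = (rng.random(4000) < special.expit(-0.3 + x)).astype(float)
            f = fit_logit(y, x[:, None])
            c, d, _ = hosmer_lemeshow(f, groups=10)
            chis.append(c); dfs.append(d)
        # mean of chi2(df) is df; allow generous Monte-Carlo slack
        assert np.mean(chis) == pytest.approx(np.mean(dfs), abs=2.0)

    def test_too_few_patterns_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        f = fit_logit(y, np.empty((20, 0)))
        with pytest.raises(ValueError):
            hosmer_lemeshow(f)


class TestVif:
    def test_orthogonal_terms_unity(self, rng):
        X = np.kron(np.eye(2), np.ones(8)).T[:, :2]
        X = np.column_stack([np.r_[np.ones(8), -np.ones(8)],
                             np.r_[np.ones(4), -np.ones(4),
                                   np.ones(4), -np.ones(4)]])
        out = variance_inflation(X)
        for v in out["vif"].values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_term_infinite(self, rng):
        x = rng.normal(size=100)
        out = variance_inflation(np.column_stack([x, x]))
        assert np.isinf(out["mean"])

    def test_matches_direct_r2(self, rng):
        X = rng.normal(size=(500, 3))
        X[:, 2] += 0.8 * X[:, 0]
        out = variance_inflation(X)
        j = 2
        others = np.column_stack([np.ones(500), X[:, 0], X[:, 1]])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        r2 = 1 - np.sum((X[:, j] - others @ beta) ** 2) \
            / np.sum((X[:, j] - X[:, j].mean()) ** 2)
        assert out["vif"]["x2"] == pytest.approx(1 / (1 - r2), rel=1e-9)


class TestFitStatistics:
    def test_published_battery_on_fixture(self, sht_fit):
        mcf, cs, nag = pseudo_r2(sht_fit)
        assert mcf == pytest.approx(0.186, abs=5e-4)
        assert cs == pytest.approx(0.102, abs=5e-4)
        assert nag == pytest.approx(0.232, abs=5e-4)
        aic, bic = info_criteria(sht_fit)
        assert aic == pytest.approx(117.78, abs=0.01)
        assert bic == pytest.approx(128.20, abs=0.01)
        assert sht_fit.deviance == pytest.approx(111.78, abs=0.01)

    def test_null_model_zero_r2(self):
        y = np.r_[np.ones(40), np.zeros(60)]
        f = fit_logit(y, np.empty((100, 0)))
        assert pseudo_r2(f) == pytest.approx((0.0, 0.0, 0.0), abs=1e-10)

    def test_bic_minus_aic_identity(self, sht_fit):
        aic, bic = info_criteria(sht_fit)
        assert bic - aic == pytest.approx(
            sht_fit.k * (np.log(sht_fit.n) - 2), abs=1e-9)

    def test_lr_vs_null_on_fixture(self, sht_fit, units):
        null = fit_logit(units["sht"].to_numpy(), np.empty((238, 0)))
        chi2, df, p = lr_test(null, sht_fit)
        assert chi2 == pytest.approx(25.55, abs=0.01)
        assert df == 2
        assert p < 1e-3

    def test_lr_model_vs_itself(self, sht_fit):
        chi2, df, p = lr_test(sht_fit, sht_fit)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_lr_null_rejection_rate(self, rng):
        rejections = 0
        reps = 100
        for _ in range(reps):
            x = rng.normal(size=(400, 2))
            y = (rng.random(400) < special.expit(-0.5 + x[:, 0])).astype(float)
            nested = fit_logit(y, x[:, :1])
            full = fit_logit(y, x)
            _, _, p = lr_test(nested, full)
            rejections += p < 0.05
        # binomial(100, 0.05): 3 MC SEs ~ 6.5
        assert rejections <= 12


class TestRomanoWolf:
    @staticmethod
    def _replaying(draws):
        """Resampler that replays a fixed (reps, k) draw matrix in order."""
        it = iter(draws)
        return lambda g: next(it)

    def test_single_hypothesis_equals_raw_bootstrap_p(self, rng):
        draws = rng.normal(size=(500, 1))
        stat = 2.0
        adj = romano_wolf_adjust([stat], self._replaying(draws), reps=500,
                                 seed=1)
        raw = (1 + np.sum(np.abs(draws[:, 0]) >= stat)) / 501
        assert adj[0] == pytest.approx(raw, abs=1e-12)

    def test_adjusted_dominates_raw(self, rng):
        stats_obs = np.array([0.5, 1.5, 2.5, 3.5])
        draws = rng.normal(size=(400, 4))
        adj = romano_wolf_adjust(stats_obs, self._replaying(draws), reps=400,
                                 seed=2)
        raw = [(1 + np.sum(np.abs(draws[:, j]) >= s)) / 401
               for j, s in enumerate(stats_obs)]
        assert all(a >= r - 1e-12 for a, r in zip(adj, raw))
        order = np.argsort(stats_obs)[::-1]
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_familywise_error_controlled(self, rng):
        """All-null family: FWER at alpha=0.05 within Monte-Carlo slack."""
        reps_outer = 150
        fwe = 0
        for i in range(reps_outer):
            data = rng.normal(size=(80, 4))
            tstats = data.mean(axis=0) / data.std(axis=0, ddof=1) * np.sqrt(80)

            def resampler(g, data=data, tstats=tstats):
                idx = g.integers(0, 80, 80)
                d = data[idx]
                t = d.mean(axis=0) / d.std(axis=0, ddof=1) * np.sqrt(80)
                return t - tstats

            adj = romano_wolf_adjust(np.abs(tstats), resampler, reps=150,
                                     seed=i)
            fwe += np.any(adj < 0.05)
        # alpha + 2 MC SE: 0.05*150 = 7.5, sd ~ 2.7
        assert fwe <= 14


class TestAuc:
    def test_published_auc_on_fixture(self, sht_fit):
        auc, (lo, hi) = roc_auc(sht_fit)
        assert auc == pytest.approx(0.83, abs=0.005)
        assert lo == pytest.approx(0.75, abs=0.02)
        assert hi == pytest.approx(0.90, abs=0.02)

    def test_constant_predictor_half(self):
        y = np.r_[np.ones(20), np.zeros(30)]
        f = fit_logit(y, np.empty((50, 0)))
        auc, _ = roc_auc(f)
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_brute_force(self, rng):
        x = rng.normal(size=60)
        y = (rng.random(60) < special.expit(x)).astype(float)
        f = fit_logit(y, x[:, None])
        auc, _ = roc_auc(f)
        pos = f.fitted[y == 1]
        neg = f.fitted[y == 0]
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert auc == pytest.approx(brute, abs=1e-12)

    def test_compare_model_with_itself(self, sht_fit):
        chi2, df, p = compare_auc(sht_fit, sht_fit)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_detects_auc_difference(self, rng):
        n = 2000
        strong = rng.normal(size=n)
        weak = rng.normal(size=n)
        y = (rng.random(n) < special.expit(1.8 * strong)).astype(float)
        fa = fit_logit(y, strong[:, None])
        fb = fit_logit(y, weak[:, None])
        _, _, p = compare_auc(fa, fb)
        assert p < 1e-4

    def test_delong_variance_close_to_bootstrap(self, rng):
        n = 600
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(scale=1.5, size=n)
        y = (rng.random(n) < special.expit(x1)).astype(float)
        fa = fit_logit(y, x1[:, None])
        fb = fit_logit(y, x2[:, None])
        chi2, _, _ = compare_auc(fa, fb)
        d_obs = roc_auc(fa)[0] - roc_auc(fb)[0]
        var_delong = d_obs ** 2 / chi2
        boots = []
        for _ in range(300):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            sa, sb, yy = fa.fitted[idx], fb.fitted[idx], y[idx]
            def auc_of(s):
                pos, neg = s[yy == 1], s[yy == 0]
                return np.mean((pos[:, None] > neg[None, :])
                               + 0.5 * (pos[:, None] == neg[None, :]))
            boots.append(auc_of(sa) - auc_of(sb))
        var_boot = np.var(boots, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.30)


class TestSelectModel:
    def _report(self, name, aic, bic, auc):
        return PostestimationReport(
            name=name, link_test_p=0.5, box_tidwell_p={}, box_tidwell_shift=1,
            hl_chi2=1, hl_df=5, hl_p=0.9, mean_vif=1.0, deviance=100,
            lr_chi2=10, lr_df=2, lr_p=0.001, mcfadden=0.1, cox_snell=0.1,
            nagelkerke=0.1, aic=aic, bic=bic, auc=auc, auc_ci=(0.7, 0.9))

    def test_best_battery_ranked_first(self):
        reports = [self._report("dragon", 126.96, 137.38, 0.76),
                   self._report("sedan", 132.36, 142.77, 0.72),
                   self._report("hti", 117.78, 128.20, 0.83)]
        out = select_model(reports)
        assert out["selected"] == "hti"

    def test_identical_reports_tie(self):
        out = select_model([self._report("a", 100, 110, 0.8),
                            self._report("b", 100, 110, 0.8)])
        assert out["tie"] == ["a", "b"]

    def test_order_invariance(self):
        reports = [self._report("a", 120, 130, 0.7),
                   self._report("b", 110, 125, 0.8),
                   self._report("c", 115, 128, 0.75)]
        out1 = select_model(reports)
        out2 = select_model(reports[::-1])
        assert out1["ranking"] == out2["ranking"]
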