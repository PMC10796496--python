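"""Data model, CSV round-trip, grouping and baseline two-group tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from htestrat.cohort import (CohortValidationError, GroupedCohort,
                             PatientRecord, build_grouped_cohort,
                             contingency_test, frame_to_records, mann_whitney,
                             printed_cerehetis_cohort, read_cohort,
                             records_to_frame, write_cohort)
from htestrat.scores import compute_hti
from htestrat.simulate import default_cerehetis_config, generate_cohort


def _record(i=0, **kw):
    base = dict(id=f"p{i}", arm=1, age=64.0, sex=1, nihss=11, aspects=9,
                hmca=0, af_ecg=0, glucose=6.0, prestroke_mrs=0,
                onset_to_treatment=100.0, sht=0, any_ht=0, mrs90=1, ffo=1)
    base.update(kw)
    return PatientRecord(**base)


class TestRecordValidation:
    def test_out_of_range_mrs_names_row_and_field(self, tmp_path):
        df = records_to_frame([_record(0), _record(1)])
        df.loc[1, "mrs90"] = 7
        df.loc[1, "ffo"] = 0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="row 1.*mrs90"):
            read_cohort(path)

    def test_sht_implies_any_ht(self):
        with pytest.raises(CohortValidationError, match="any_ht"):
            _record(sht=1, any_ht=0).validate()

    def test_ffo_must_match_mrs(self):
        with pytest.raises(CohortValidationError, match="ffo"):
            _record(mrs90=4, ffo=1).validate()

    def test_missing_column_reported(self):
        df = records_to_frame([_record()]).drop(columns=["nihss"])
        with pytest.raises(CohortValidationError, match="nihss"):
            frame_to_records(df)


class TestCsvRoundTrip:
    def test_three_rows_identity(self, tmp_path):
        recs = [_record(i) for i in range(3)]
        path = tmp_path / "c.csv"
        write_cohort(recs, path)
        back = read_cohort(path)
        assert len(back) == 3
        assert back == recs

    def test_synthetic_cohort_round_trip(self, tmp_path):
        recs = generate_cohort(default_cerehetis_config(n=60, seed=3))
        path = tmp_path / "s.csv"
        write_cohort(recs, path)
        back = read_cohort(path)
        for a, b in zip(recs, back):
            for f in vars(a):
                va, vb = getattr(a, f), getattr(b, f)
                if isinstance(va, float):
                    assert vb == pytest.approx(va)
                else:
                    assert vb == va


class TestGrouping:
    def test_fixture_expand_regroup_is_identity(self, grouped, units):
        recs = frame_to_records(
            pd.DataFrame({
                "id": [str(i) for i in range(len(units))],
                "arm": units.arm, "age": 64.0, "sex": 0,
                "nihss": 5, "aspects": 9, "hmca": 0, "af_ecg": 0,
                "glucose": 6.0, "prestroke_mrs": 0, "onset_to_treatment": 90.0,
                "sht": units.sht, "any_ht": units.any_ht,
                "mrs90": np.nan, "ffo": units.ffo,
            }),
            validate=False,
        )
        regrouped = build_grouped_cohort(recs, units.hti.tolist())
        expect = {(s.score, s.arm): (s.n, dict(s.events))
                  for s in grouped.strata if s.n > 0}
        got = {(s.score, s.arm): (s.n, dict(s.events))
               for s in regrouped.strata}
        assert got == expect

    def test_single_record(self):
        g = build_grouped_cohort([_record(any_ht=1)], [2])
        assert len(g.strata) == 1
        assert g.strata[0].n == 1
        assert g.strata[0].events["any_ht"] == 1

    def test_random_cohort_sums_match_brute_force(self):
        recs = generate_cohort(default_cerehetis_config(n=300, seed=9))
        score = [compute_hti(r.aspects, r.nihss, r.hmca, r.af_ecg)
                 for r in recs]
        g = build_grouped_cohort(recs, score)
        assert g.n == 300
        for s in g.strata:
            members = [r for r, sc in zip(recs, score)
                       if sc == s.score and r.arm == s.arm]
            assert s.n == len(members)
            for out in ("sht", "any_ht", "ffo"):
                assert s.events[out] == sum(getattr(r, out) for r in members)

    def test_event_exceeding_n_rejected(self):
        from htestrat.cohort import Stratum
        with pytest.raises(ValueError, match="events"):
            Stratum(0, 1, 5, {"sht": 6})


class TestPrintedCohort:
    def test_total_and_arm_sizes(self, grouped):
        assert grouped.n == 238
        totals = grouped.arm_totals("sht")
        assert totals[1][1] == 91
        assert totals[0][1] == 147

    def test_event_margins(self, grouped):
        assert grouped.arm_totals("sht")[1][0] == 3
        assert grouped.arm_totals("sht")[0][0] == 17
        assert grouped.arm_totals("any_ht")[1][0] == 15
        assert grouped.arm_totals("any_ht")[0][0] == 37
        assert grouped.arm_totals("ffo")[1][0] == 69
        assert grouped.arm_totals("ffo")[0][0] == 98

    def test_stratum_sizes_by_arm(self, grouped):
        n_by = {(s.score, s.arm): s.n for s in grouped.strata}
        assert [n_by[(h, 1)] for h in range(5)] == [34, 34, 17, 6, 0]
        assert [n_by[(h, 0)] for h in range(5)] == [67, 37, 30, 11, 2]

    def test_json_round_trip(self, grouped):
        back = GroupedCohort.from_dict(grouped.to_dict())
        assert back.to_dict() == grouped.to_dict()


class TestContingency:
    @pytest.mark.parametrize("cells,p_expected", [
        ((3, 88, 17, 130), 0.025),    # symptomatic HT endpoint
        ((15, 76, 37, 110), 0.115),   # any HT endpoint
        ((69, 22, 98, 49), 0.133),    # favorable outcome endpoint
    ])
    def test_published_endpoint_pvalues(self, cells, p_expected):
        _, p = contingency_test(*cells)
        assert p == pytest.approx(p_expected, abs=5e-4)

    def test_identical_proportions(self):
        chi2, p = contingency_test(10, 90, 10, 90)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        a, b, c, d = 15, 76, 37, 110
        n = a + b + c + d
        chi2_direct = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = contingency_test(a, b, c, d)
        assert chi2 == pytest.approx(chi2_direct, rel=1e-12)

    def test_transpose_invariance(self):
        assert contingency_test(3, 88, 17, 130) == \
            pytest.approx(contingency_test(3, 17, 88, 130))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            contingency_test(0, 0, 5, 7)


class TestMannWhitney:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0] * 4
        _, p = mann_whitney(x, list(x))
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_gives_zero_u(self):
        u, _ = mann_whitney([1, 2, 3], [10, 11, 12])
        assert min(u, 9 - u) == 0

    def test_exact_p_matches_permutation_oracle(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(loc=0.8, size=6)
        u_obs, p = mann_whitney(x, y)
        pooled = np.r_[x, y]
        nx = len(x)
        count = 0
        total = 0
        for pick in combinations(range(len(pooled)), nx):
            xs = pooled[list(pick)]
            ys = np.delete(pooled, list(pick))
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
            stat = max(u, nx * len(ys) - u)
            obs = max(u_obs, nx * len(ys) - u_obs)
            count += stat >= obs
            total += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
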