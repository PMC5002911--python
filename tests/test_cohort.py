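"""Cohort statistics: CV arithmetic, repeatability tables, ANOVA layer,
and PHV-jump correlations."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import muscleox as mx


def _indices(phv=10.0, ttp=25.0, miv=-8.0, ttr=120.0, recovered=True, muscle="gastrocnemius"):
    return mx.BoldIndices(phv=phv, ttp=ttp, miv=miv,
                          ttr=ttr if recovered else None, recovered=recovered, muscle=muscle)


def _record(sid, group="controls", visit=1, phv=10.0, muscles=("gastrocnemius",), **kw):
    return mx.SubjectRecord(
        subject_id=sid, group=group, visit=visit,
        indices={m: _indices(phv=phv, muscle=m) for m in muscles}, **kw,
    )


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(12.9, 5.8, 45.0), (10.0, 0.0, 0.0), (134.1, 21.5, 16.0), (-13.3, 4.3, 32.3)],
    )
    def test_worked_examples(self, mean, sd, expected):
        assert round(mx.coefficient_of_variation(mean, sd), 1) == expected

    def test_zero_mean_rejected(self):
        with pytest.raises(mx.StatsError, match="zero mean"):
            mx.coefficient_of_variation(0.0, 1.0)

    @given(
        mean=st.floats(0.5, 1e3), sd=st.floats(0.0, 1e3), c=st.floats(1e-3, 1e3)
    )
    def test_scale_invariance(self, mean, sd, c):
        a = mx.coefficient_of_variation(mean, sd)
        b = mx.coefficient_of_variation(c * mean, c * sd)
        assert a == pytest.approx(b, rel=1e-9)


class TestRepeatability:
    def _paired_cohort(self, values1, values2):
        recs = []
        for i, (a, b) in enumerate(zip(values1, values2)):
            recs.append(_record(f"c{i}", visit=1, phv=a))
            recs.append(_record(f"c{i}", visit=2, phv=b))
        return recs

    def test_identical_visits_have_equal_cv_and_undefined_p(self):
        vals = [8.0, 10.0, 12.0, 14.0]
        table = mx.repeatability_table(self._paired_cohort(vals, vals), parameters=("phv",))
        row = table[0]
        assert row.visit1_cv == pytest.approx(row.visit2_cv)
        assert math.isnan(row.paired_p)  # zero-variance differences: reported as undefined
        assert row.n_pairs == 4

    def test_visit_columns_reproduce_plain_moments(self):
        v1, v2 = [8.0, 10.0, 12.0, 15.0], [9.0, 11.0, 10.0, 16.0]
        row = mx.repeatability_table(self._paired_cohort(v1, v2), parameters=("phv",))[0]
        assert row.visit1_mean == pytest.approx(np.mean(v1))
        assert row.visit1_sd == pytest.approx(np.std(v1, ddof=1))
        assert row.visit2_mean == pytest.approx(np.mean(v2))
        assert row.paired_p == pytest.approx(sps.ttest_rel(v1, v2).pvalue)

    def test_requires_two_paired_controls(self):
        recs = [_record("c0", visit=1), _record("c0", visit=2), _record("c1", visit=1)]
        with pytest.raises(mx.StatsError, match="2 control subjects"):
            mx.repeatability_table(recs)

    def test_paired_p_uniform_under_null(self):
        # two visits drawn from the same per-subject truth + noise: the visit
        # comparison should reject at ~alpha
        rej = 0
        reps = 300
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            truth = rng.normal(12, 4, size=10)
            recs = self._paired_cohort(truth + rng.normal(0, 2, 10),
                                       truth + rng.normal(0, 2, 10))
            row = mx.repeatability_table(recs, parameters=("phv",))[0]
            rej += row.paired_p < 0.05
        assert 0.01 <= rej / reps <= 0.10

    def test_cohort_cv_matches_population_moments(self):
        # soleus-like PHV population (mean 12.9, SD 5.8) at n=10 per visit:
        # the tabulated CV should scatter around 45 %
        cvs = []
        for seed in range(50):
            spec = mx.CohortSpec(
                group_sizes={"controls": 10},
                muscles=("soleus",),
                simulate_curves=False,
                within_subject_frac=0.3,
                seed=seed,
            )
            table = mx.repeatability_table(mx.simulate_cohort(spec), parameters=("phv",))
            cvs.append(table[0].visit1_cv)
        assert 38.0 <= np.mean(cvs) <= 52.0


class TestAnova:
    def _two_group_records(self, rng, n=12, delta=0.0):
        recs = []
        for i in range(n):
            recs.append(_record(f"l{i}", group="linemen", phv=float(rng.normal(12, 3))))
            recs.append(_record(f"c{i}", group="controls", phv=float(rng.normal(12 + delta, 3))))
        return recs

    def test_two_groups_equals_t_test_squared(self, rng):
        recs = self._two_group_records(rng, delta=2.0)
        res = [r for r in mx.group_muscle_anova(recs, "phv") if r.factor == "group"][0]
        x = [r.indices["gastrocnemius"].phv for r in recs if r.group == "linemen"]
        y = [r.indices["gastrocnemius"].phv for r in recs if r.group == "controls"]
        t, p = sps.ttest_ind(x, y)
        assert res.anova_f == pytest.approx(t**2, rel=1e-9)
        assert res.anova_p == pytest.approx(p, rel=1e-9)

    def test_identical_samples_give_posthoc_p_of_one(self):
        # three groups holding literally the same sample: all pairwise
        # comparisons are exact ties
        vals = list(np.linspace(5, 20, 30))
        recs = []
        for g in mx.GROUPS:
            for i, v in enumerate(vals):
                recs.append(_record(f"{g}{i}", group=g, phv=v))
        res = [r for r in mx.group_muscle_anova(recs, "phv", alpha=1.01)
               if r.factor == "group"][0]
        assert all(p == pytest.approx(1.0) for p in res.posthoc.values())

    def test_normality_not_assessable_below_eight(self, rng):
        recs = self._two_group_records(rng, n=5)
        res = [r for r in mx.group_muscle_anova(recs, "phv") if r.factor == "group"][0]
        assert all(math.isnan(c.normality_p) for c in res.cells.values())

    def test_muscle_factor_compares_within_group(self, rng):
        muscles = ("gastrocnemius", "soleus")
        recs = []
        for i in range(10):
            indices = {
                "gastrocnemius": _indices(phv=float(rng.normal(8, 2)), muscle="gastrocnemius"),
                "soleus": _indices(phv=float(rng.normal(16, 2)), muscle="soleus"),
            }
            recs.append(mx.SubjectRecord(subject_id=f"c{i}", group="controls",
                                         visit=1, indices=indices))
        res = [r for r in mx.group_muscle_anova(recs, "phv") if r.factor == "muscle"]
        assert len(res) == 1 and res[0].stratum == "controls"
        assert res[0].anova_p < 0.01
        assert set(res[0].cells) == set(muscles)

    def test_zero_variance_cell_rejected(self):
        recs = [_record(f"l{i}", group="linemen", phv=5.0) for i in range(4)]
        recs += [_record(f"c{i}", group="controls", phv=float(i)) for i in range(4)]
        with pytest.raises(mx.StatsError, match="zero variance"):
            mx.group_muscle_anova(recs, "phv")

    def test_ttr_uses_recovered_cases_only(self, rng):
        recs = []
        for i in range(8):
            idx = _indices(phv=float(rng.normal(12, 3)), ttr=float(rng.normal(120, 20)))
            recs.append(mx.SubjectRecord(subject_id=f"l{i}", group="linemen",
                                         visit=1, indices={"gastrocnemius": idx}))
        for i in range(8):
            idx = _indices(phv=10.0 + i, ttr=100.0 + 5 * i, recovered=i > 1)
            recs.append(mx.SubjectRecord(subject_id=f"c{i}", group="controls",
                                         visit=1, indices={"gastrocnemius": idx}))
        res = [r for r in mx.group_muscle_anova(recs, "ttr") if r.factor == "group"][0]
        assert res.cells["controls"].n == 6  # two non-recovered subjects dropped


class TestJumpCorrelation:
    def test_perfect_linear_relation(self):
        recs = [
            _record(f"s{i}", phv=float(i + 1), vertical_jump=40.0 + 2.0 * i)
            for i in range(8)
        ]
        res = mx.jump_correlation(recs, "gastrocnemius", "vertical")
        assert res.r == pytest.approx(1.0)
        assert res.n == 8

    def test_excluded_and_missing_subjects_are_dropped(self):
        recs = [
            _record(f"s{i}", phv=float(i), vertical_jump=40.0 + i + (i % 3))
            for i in range(2, 8)
        ]
        recs.append(_record("out", phv=99.0, vertical_jump=1.0,
                            excluded=True, exclusion_reason="outlier"))
        recs.append(_record("nojump", phv=5.0))  # no jump measurement
        res = mx.jump_correlation(recs, "gastrocnemius", "vertical")
        assert res.n == 6

    def test_insufficient_subjects_rejected(self):
        recs = [_record("a", phv=1.0, vertical_jump=10.0),
                _record("b", phv=2.0, vertical_jump=12.0)]
        with pytest.raises(mx.StatsError, match=">= 3"):
            mx.jump_correlation(recs, "gastrocnemius", "vertical")

    def test_zero_variance_rejected(self):
        recs = [_record(f"s{i}", phv=5.0, vertical_jump=40.0 + i) for i in range(5)]
        with pytest.raises(mx.StatsError, match="variance"):
            mx.jump_correlation(recs, "gastrocnemius", "vertical")


class TestRecords:
    def test_visit_two_only_for_controls(self):
        with pytest.raises(mx.StatsError, match="visit 2"):
            _record("x", group="linemen", visit=2)

    def test_excluded_needs_reason(self):
        with pytest.raises(mx.StatsError, match="reason"):
            _record("x", excluded=True)

    def test_frame_roundtrip(self):
        spec = mx.CohortSpec(muscles=("gastrocnemius", "soleus"),
                             simulate_curves=False, seed=3)
        records = mx.simulate_cohort(spec)
        df = mx.records_to_frame(records)
        back = mx.records_from_frame(df)
        assert len(back) == len(records)
        orig = {(r.subject_id, r.visit): r for r in records}
        for rec in back:
            ref = orig[(rec.subject_id, rec.visit)]
            assert rec.group == ref.group
            for m in rec.indices:
                assert rec.indices[m].phv == pytest.approx(ref.indices[m].phv)
                assert rec.indices[m].recovered == ref.indices[m].recovered
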