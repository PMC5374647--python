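"""Kaplan-Meier and log-rank machinery, checked against independent routes."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from oncothemes import kaplan_meier, logrank_test, stratified_survival


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = kaplan_meier([5, 10, 15], [0, 0, 0])
        assert km.empty  # no event times -> S stays 1 everywhere

    def test_no_censoring_closed_form(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        assert list(km["survival"]) == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_hand_computed_with_censoring(self):
        # times 2,3+,5,7,8+ : S(2)=4/5, S(5)=4/5*2/3, S(7)=4/5*2/3*1/2
        km = kaplan_meier([2, 3, 5, 7, 8], [1, 0, 1, 1, 0])
        assert list(km["time"]) == [2, 5, 7]
        assert list(km["survival"]) == pytest.approx([4 / 5, 8 / 15, 4 / 15])

    def test_matches_exact_rational_product_limit(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 15))
            times = rng.integers(1, 8, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            km = kaplan_meier(times, events)
            # independent oracle in exact rational arithmetic
            surv = Fraction(1)
            expected = {}
            for t in sorted(set(times[events == 1])):
                at_risk = int(np.sum(times >= t))
                d = int(np.sum((times == t) & (events == 1)))
                surv *= Fraction(at_risk - d, at_risk)
                expected[float(t)] = surv
            for row in km.itertuples():
                assert row.survival == pytest.approx(float(expected[row.time]), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0], [1])

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=50)
        events = rng.integers(0, 2, size=50)
        km = kaplan_meier(times, events)
        lf = KaplanMeierFitter().fit(times, events)
        for row in km.itertuples():
            assert row.survival == pytest.approx(
                float(lf.survival_function_at_times(row.time).iloc[0]), abs=1e-10
            )


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 4, 5, 6] * 2
        events = [1, 1, 0, 1, 0, 1] * 2
        groups = ["a"] * 6 + ["b"] * 6
        stat, df, p = logrank_test(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_two_group_fixture_matches_brute_force(self):
        # fixed 6+6 cohort with ties and censoring
        times = [3, 5, 5, 8, 10, 12, 2, 4, 5, 9, 9, 11]
        events = [1, 1, 0, 1, 0, 1, 1, 1, 1, 1, 0, 1]
        groups = [0] * 6 + [1] * 6
        stat, df, p = logrank_test(times, events, groups)
        # independent brute-force O-E / variance accumulation
        t_arr, e_arr, g_arr = map(np.asarray, (times, events, groups))
        oe = 0.0
        var = 0.0
        for t in sorted(set(t_arr[e_arr == 1])):
            risk = t_arr >= t
            n = risk.sum()
            n1 = (risk & (g_arr == 0)).sum()
            d = ((t_arr == t) & (e_arr == 1)).sum()
            d1 = ((t_arr == t) & (e_arr == 1) & (g_arr == 0)).sum()
            oe += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert stat == pytest.approx(oe**2 / var, rel=1e-10)
        assert df == 1

    def test_two_group_statistic_is_squared_standardized_sum(self, rng):
        times = rng.exponential(5, size=40)
        events = rng.integers(0, 2, size=40)
        events[0] = 1
        groups = rng.integers(0, 2, size=40)
        if len(np.unique(groups)) < 2:
            groups[0], groups[1] = 0, 1
        stat, df, _ = logrank_test(times, events, groups)
        assert df == 1
        assert stat >= 0.0

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = rng.exponential(5, size=90)
        events = rng.integers(0, 2, size=90)
        events[:3] = 1
        groups = rng.integers(0, 3, size=90)
        stat, df, p = logrank_test(times, events, groups)
        ref = multivariate_logrank_test(times, groups, events)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)

    def test_planted_hazard_ratio_detected(self):
        gen = np.random.default_rng(11)
        t0 = gen.exponential(1.0, size=100)
        t1 = gen.exponential(1.0 / 3.0, size=100)  # hazard ratio 3
        times = np.r_[t0, t1]
        events = np.ones(200, dtype=int)
        groups = np.r_[np.zeros(100), np.ones(100)]
        _, _, p = logrank_test(times, events, groups)
        assert p < 0.05

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], ["a", "b"])


def _cohort(gen, n_per_cluster, hazards, ctype="CT1"):
    rows = []
    i = 0
    for c, (n, h) in enumerate(zip(n_per_cluster, hazards)):
        for _ in range(n):
            t = gen.exponential(1.0 / h)
            rows.append((f"s{i}", ctype, t, 1, c))
            i += 1
    return pd.DataFrame(
        rows, columns=["sample_id", "cancer_type", "time", "event", "cluster_id"]
    )


class TestStratifiedSurvival:
    def test_small_cluster_excluded_only_in_filtered_run(self):
        gen = np.random.default_rng(3)
        df = _cohort(gen, [40, 40, 24], [0.01, 0.03, 0.02])
        rep = stratified_survival(df, min_cluster_size=25)
        runs = dict(zip(rep.table["run"], rep.table["clusters_used"]))
        assert runs["all"] == "0|1|2"
        assert runs["filtered"] == "0|1"

    def test_zero_min_size_makes_runs_identical(self):
        gen = np.random.default_rng(4)
        df = _cohort(gen, [30, 10], [0.01, 0.04])
        rep = stratified_survival(df, min_cluster_size=0)
        tab = rep.table.set_index("run")
        assert tab.loc["all", "statistic"] == pytest.approx(
            tab.loc["filtered", "statistic"]
        )

    def test_single_cluster_cancer_type_skipped(self):
        gen = np.random.default_rng(5)
        df = _cohort(gen, [30], [0.01])
        rep = stratified_survival(df)
        assert rep.table.empty

    def test_cluster_dependent_hazards_significant(self):
        gen = np.random.default_rng(6)
        frames = [
            _cohort(gen, [40, 40], [0.002, 0.006], ctype=ct) for ct in ("CT1", "CT2")
        ]
        rep = stratified_survival(pd.concat(frames, ignore_index=True))
        filt = rep.table[rep.table["run"] == "filtered"]
        assert set(filt["cancer_type"]) == {"CT1", "CT2"}
        assert (filt["p"] < 0.05).all()

    def test_km_curves_emitted_per_cluster(self):
        gen = np.random.default_rng(8)
        df = _cohort(gen, [30, 30], [0.01, 0.02])
        rep = stratified_survival(df)
        assert ("CT1", "all", 0) in rep.curves
        assert ("CT1", "filtered", 1) in rep.curves
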