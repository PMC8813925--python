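"""Triage criteria, contingency trend statistics, KM/log-rank."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from targetomics import synthetic_data as sd
from targetomics import triage_survival as ts
from targetomics.io_tables import Cohort


def _cohort(expr, cna=None, stages=None):
    samples = list(expr.columns)
    if cna is None:
        cna = pd.DataFrame(0, index=expr.index, columns=samples, dtype=int)
    if stages is None:
        stages = pd.Series(0, index=samples)
    return Cohort(
        expression=expr,
        stage=stages,
        survival_time=pd.Series(1.0, index=samples),
        survival_event=pd.Series(
            np.zeros(len(samples), dtype=int), index=samples
        ),
        cna_calls=cna,
    )


class TestAlterationFrequency:
    def _c(self):
        samples = [f"s{i}" for i in range(4)]
        expr = pd.DataFrame(
            [[1.0] * 4] * 2, index=["g1", "g2"], columns=samples
        )
        cna = pd.DataFrame(
            [[2, 1, 0, -1], [2, 1, 1, 0]],
            index=["g1", "g2"], columns=samples,
        )
        return _cohort(expr, cna)

    def test_single_gene_levels(self):
        c = self._c()
        assert ts.alteration_frequency(c, "g1", {2}) == 0.25
        assert ts.alteration_frequency(c, "g1", {1, 2}) == 0.50

    def test_co_alteration_needs_both(self):
        c = self._c()
        assert ts.alteration_frequency(c, ["g1", "g2"], {1, 2}) == 0.5

    def test_empty_levels(self):
        assert ts.alteration_frequency(self._c(), "g1", set()) == 0.0

    def test_absent_gene(self):
        with pytest.raises(KeyError):
            ts.alteration_frequency(self._c(), "nope", {2})


class TestProgressionCorrelation:
    def _staged(self, means, n_per_stage=5, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        values, stages, samples = [], [], []
        for s, m in enumerate(means):
            for i in range(n_per_stage):
                samples.append(f"s{s}_{i}")
                stages.append(s)
                values.append(m + rng.normal(0, noise))
        expr = pd.DataFrame([values], index=["g"], columns=samples)
        return _cohort(expr, stages=pd.Series(stages, index=samples))

    def test_increasing_means_give_rho_one(self):
        c = self._staged([0, 1, 2, 3, 4, 5])
        rho, p = ts.progression_correlation(c, "g")
        assert rho == pytest.approx(1.0)

    def test_flat_means_near_zero(self):
        c = self._staged([1, 1, 1, 1, 1, 1], noise=0.05)
        rho, _ = ts.progression_correlation(c, "g")
        assert abs(rho) < 0.8  # no systematic trend

    def test_planted_monotone_stage_effect_detected(self):
        sig = sd.random_signature(seed=8)
        cohort, _ = sd.simulate_cohort(
            sd.SimParams(seed=8, noise_sd=0.3), sig,
            n_samples=600, n_stages=6, stage_effect=1.0,
        )
        gene = sorted(sig.genes)[0]
        rho, p = ts.progression_correlation(cohort, gene)
        assert rho > 0.9
        assert p < 0.01

    def test_single_stage_rejected(self):
        c = self._staged([1.0])
        with pytest.raises(ValueError):
            ts.progression_correlation(c, "g")


class TestTriage:
    def _catalog(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "amp_freq_a": rng.uniform(0, 0.3, n),
                "amp_freq_b": rng.uniform(0, 0.3, n),
                "amp_freq_c": rng.uniform(0, 0.3, n),
                "progression_rho": rng.uniform(0.5, 1.0, n),
                "progression_p": rng.uniform(0, 0.05, n),
                "druggable": rng.random(n) < 0.4,
            },
            index=[f"G{i:03d}" for i in range(n)],
        )

    def test_venn_counts_match_brute_force(self):
        cat = self._catalog()
        res = ts.triage_targets(cat)
        c1 = {
            g for g in cat.index
            if sum(cat.loc[g, f"amp_freq_{c}"] > 0.10
                   for c in "abc") >= 2
        }
        c2 = {
            g for g in cat.index
            if cat.loc[g, "progression_rho"] > 0.9
            and cat.loc[g, "progression_p"] < 0.01
        }
        c3 = {g for g in cat.index if cat.loc[g, "druggable"]}
        sets = {"c1": c1, "c2": c2, "c3": c3}
        for r in range(4):
            for combo in itertools.combinations(("c1", "c2", "c3"), r):
                key = frozenset(combo)
                region = set(cat.index)
                for crit in ("c1", "c2", "c3"):
                    region &= sets[crit] if crit in key else (
                        set(cat.index) - sets[crit]
                    )
                assert res.venn_counts[key] == len(region)
        assert set(res.intersection) == c1 & c2 & c3

    def test_intersection_sorted_by_amp_freq(self):
        cat = self._catalog(seed=1)
        res = ts.triage_targets(cat)
        freqs = [
            res.table.loc[g, "max_amp_freq"] for g in res.intersection
        ]
        assert freqs == sorted(freqs, reverse=True)

    def test_monotone_in_thresholds(self):
        cat = self._catalog(seed=2)
        loose = ts.triage_targets(cat, amp_freq_min=0.05, rho_min=0.8,
                                  p_max=0.05)
        tight = ts.triage_targets(cat, amp_freq_min=0.15, rho_min=0.95,
                                  p_max=0.005)
        assert set(tight.intersection) <= set(loose.intersection)

    def test_missing_inputs_fail_criterion(self):
        cat = self._catalog(seed=3, n=5)
        cat.loc["G000", "progression_rho"] = np.nan
        res = ts.triage_targets(cat)
        assert not res.table.loc["G000", "meets_c2"]


class TestTrendEffectSize:
    def test_flat_table(self):
        r = ts.trend_effect_size([[10, 10], [10, 10]])
        assert r.chi2 == pytest.approx(0.0)
        assert r.cramers_v == pytest.approx(0.0)
        assert r.label == "weak"

    def test_perfect_association(self):
        r = ts.trend_effect_size([[10, 0], [0, 10]])
        assert r.cramers_v == pytest.approx(1.0)
        assert r.label == "strong"

    def test_labels_at_published_cutoffs(self):
        # construct a table with V ~ 0.15 -> weak
        r = ts.trend_effect_size([[115, 85], [85, 115]])
        assert 0.1 < r.cramers_v < 0.2
        assert r.label == "weak"
        r2 = ts.trend_effect_size([[150, 50], [50, 150]])
        assert 0.2 <= r2.cramers_v < 0.6
        assert r2.label == "moderate"

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 50, size=(r, c))
            mine = ts.trend_effect_size(table)
            chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
            assert mine.chi2 == pytest.approx(chi2, rel=1e-10)
            assert mine.p == pytest.approx(p, rel=1e-10)
            v = np.sqrt(chi2 / (table.sum() * (min(r, c) - 1)))
            assert mine.cramers_v == pytest.approx(v, rel=1e-10)
            assert 0 <= mine.cramers_v <= 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            ts.trend_effect_size([[0, 0], [5, 5]])


class TestStratify:
    def _c(self, values):
        samples = [f"s{i}" for i in range(len(values))]
        return _cohort(
            pd.DataFrame([values], index=["g"], columns=samples)
        )

    def test_median_split(self):
        labels, cut = ts.stratify_by_expression(
            self._c([1.0, 2.0, 3.0, 4.0]), "g"
        )
        assert cut == 2.5
        assert (labels == ["low", "low", "high", "high"]).all()

    def test_tertile_split(self):
        labels, cuts = ts.stratify_by_expression(
            self._c(list(range(1, 10))), "g", method="tertile"
        )
        assert (labels.value_counts() == 3).all()

    def test_custom_cut(self):
        labels, _ = ts.stratify_by_expression(
            self._c([1.0, 2.0, 3.0, 4.0]), "g", method="custom", cut=2.5
        )
        assert (labels == "high").sum() == 2

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError):
            ts.stratify_by_expression(self._c([1.0, 1.0, 1.0]), "g")


def _brute_force_logrank(times, events, groups, label_a):
    """Independent risk-set tabulation oracle."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in_a = np.asarray(groups) == label_a
    obs_a = exp_a = var = 0.0
    for ti in sorted(set(times[events == 1])):
        at = times >= ti
        n, na = at.sum(), (at & in_a).sum()
        d = int(((times == ti) & (events == 1)).sum())
        da = int(((times == ti) & (events == 1) & in_a).sum())
        obs_a += da
        exp_a += d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return obs_a, exp_a, var


class TestKaplanMeierLogrank:
    def test_curve_non_increasing_and_matches_empirical(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        e = np.ones(40, dtype=int)  # no censoring
        curve = ts.km_curve(t, e)
        assert (np.diff(curve["survival"]) <= 1e-12).all()
        # uncensored KM equals the empirical survival function
        for _, row in curve.iterrows():
            emp = (t > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_identical_groups(self):
        t = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        e = np.ones(10, dtype=int)
        g = np.array(["a"] * 5 + ["b"] * 5)
        res = ts.km_logrank(t, e, g)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.hr == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            ts.km_logrank([1, 2], [0, 0], ["a", "b"])

    def test_eight_subject_hand_example(self):
        """O/E and chi2 agree with an enumerated risk-table oracle."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        g = np.array(["a"] * 4 + ["b"] * 4)
        res = ts.km_logrank(t, e, g)
        obs_a, exp_a, var = _brute_force_logrank(t, e, g, "a")
        assert res.observed["a"] == pytest.approx(obs_a)
        assert res.expected["a"] == pytest.approx(exp_a)
        assert res.logrank_chi2 == pytest.approx(
            (obs_a - exp_a) ** 2 / var
        )
        # frozen values from the oracle tabulation
        assert obs_a == pytest.approx(3.0)
        assert exp_a == pytest.approx(1.6071428571428572)
        assert var == pytest.approx(0.8456632653061225)
        assert res.hr == pytest.approx(
            (3.0 / exp_a) / (3.0 / (6 - exp_a))
        )

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        t = rng.exponential(10, 60)
        e = (rng.random(60) < 0.7).astype(int)
        g = np.array(["a"] * 30 + ["b"] * 30)
        res = ts.km_logrank(t, e, g)
        ref = logrank_test(t[g == "a"], t[g == "b"],
                           e[g == "a"], e[g == "b"])
        assert res.logrank_chi2 == pytest.approx(
            ref.test_statistic, rel=1e-9
        )
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)
        kmf = KaplanMeierFitter().fit(t[g == "a"], e[g == "a"])
        mine = ts.km_curve(t[g == "a"], e[g == "a"])
        for _, row in mine.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["time"])), rel=1e-9
            )

    def test_planted_hazard_ratio_recovered(self):
        t, e, g = sd.simulate_two_group_survival(500, 2.0, seed=3)
        res = ts.km_logrank(t, e, g)
        assert abs(res.hr - 2.0) <= 0.25
        assert res.hr_ci[0] < res.hr < res.hr_ci[1]

    def test_unit_hazard_ratio_when_groups_identical_in_law(self):
        t, e, g = sd.simulate_two_group_survival(400, 1.0, seed=4)
        res = ts.km_logrank(t, e, g)
        assert 0.8 < res.hr < 1.25
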