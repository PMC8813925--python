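"""Welch/BH/Stouffer kernels and the consensus differential caller."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from targetomics import diffprot as dp
from targetomics import synthetic_data as sd
from targetomics.io_tables import DesignError, QuantMatrix


def _matrix(values, design, log_scale=True):
    data = pd.DataFrame(
        values, index=[f"F{i}" for i in range(len(values))],
        columns=list(design),
    )
    return QuantMatrix(data=data, design=design, log_scale=log_scale)


DESIGN_3V3 = {f"a{i}": "A" for i in range(3)} | {
    f"b{i}": "B" for i in range(3)
}


class TestPrepareMatrix:
    def test_feature_below_min_valid_excluded(self):
        m = _matrix(
            [[4, 4, np.nan, 8, 8, 8], [4, 4, 4, 8, 8, 8]],
            DESIGN_3V3, log_scale=False,
        )
        _, testable = dp.prepare_matrix(m, min_valid=3)
        assert not testable["F0"]
        assert testable["F1"]

    def test_log2_transform(self):
        m = _matrix([[8.0] * 6], DESIGN_3V3, log_scale=False)
        logged, _ = dp.prepare_matrix(m, min_valid=3)
        assert (logged.data.iloc[0] == 3.0).all()
        assert logged.log_scale

    def test_complete_matrix_keeps_everything(self):
        m = _matrix([[4] * 6, [5] * 6], DESIGN_3V3, log_scale=False)
        _, testable = dp.prepare_matrix(m, min_valid=3)
        assert testable.all()

    def test_small_group_is_design_error(self):
        design = {"a0": "A", "a1": "A", "b0": "B", "b1": "B", "b2": "B"}
        m = _matrix([[4] * 5], design, log_scale=False)
        with pytest.raises(DesignError):
            dp.prepare_matrix(m, min_valid=3)

    def test_min_valid_lower_bound(self, small_matrix):
        with pytest.raises(ValueError):
            dp.prepare_matrix(small_matrix, min_valid=1)


class TestWelch:
    def test_identical_groups(self):
        m = _matrix([[1, 2, 3, 1, 2, 3]], DESIGN_3V3)
        r = dp.welch_contrast(m, "A", "B").iloc[0]
        assert r["log2fc"] == 0
        assert r["p"] == 1.0

    def test_textbook_values(self):
        """a=[13,14,15] vs b=[10,11,12]: closed-form Welch t/df/p."""
        m = _matrix([[13, 14, 15, 10, 11, 12]], DESIGN_3V3)
        r = dp.welch_contrast(m, "A", "B").iloc[0]
        assert r["log2fc"] == pytest.approx(3.0)
        assert r["t_stat"] == pytest.approx(3.674, abs=1e-3)
        assert r["df"] == pytest.approx(4.0, abs=1e-9)
        assert r["p"] == pytest.approx(0.0213, abs=5e-4)

    def test_degenerate_equal_constants(self):
        m = _matrix([[5, 5, 5, 5, 5, 5]], DESIGN_3V3)
        r = dp.welch_contrast(m, "A", "B").iloc[0]
        assert r["p"] == 1.0

    def test_degenerate_distinct_constants_floored(self):
        m = _matrix([[6, 6, 6, 5, 5, 5]], DESIGN_3V3)
        r = dp.welch_contrast(m, "A", "B").iloc[0]
        assert 0 < r["p"] < 1e-300

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.normal(), 1, nb)
            t, df, p, diff = dp._welch_arrays(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert df == pytest.approx(ref.df, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestBH:
    def test_hand_example(self):
        q = dp.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert dp.bh_adjust(np.array([0.04]))[0] == pytest.approx(0.04)

    def test_all_equal(self):
        q = dp.bh_adjust(np.full(7, 0.5))
        assert q == pytest.approx(np.full(7, 0.5))

    def test_empty(self):
        assert dp.bh_adjust(np.array([])).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dp.bh_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                 max_size=40)
    )
    def test_matches_brute_force(self, pvals):
        """q_i = min over j with p_j >= p_i of p_j * m / rank_j."""
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        brute = np.empty(m)
        best = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            best = min(best, p[i] * m / rank)
            brute[i] = min(best, 1.0)
        assert dp.bh_adjust(p) == pytest.approx(brute, rel=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert dp.bh_adjust(p) == pytest.approx(q_ref, rel=1e-12)


def _contrast_frame(ps, fcs):
    return pd.DataFrame(
        {"p": ps, "log2fc": fcs},
        index=[f"F{i}" for i in range(len(ps))],
    )


class TestStouffer:
    def test_two_clones_closed_form(self):
        per = {
            "c1": _contrast_frame([0.05], [1.0]),
            "c2": _contrast_frame([0.05], [0.5]),
        }
        res = dp.stouffer_combine(per)
        z = 2 * sps.norm.isf(0.025) / np.sqrt(2)
        assert res.table["combined_z"].iloc[0] == pytest.approx(z, rel=1e-9)
        assert res.table["combined_p"].iloc[0] == pytest.approx(
            2 * sps.norm.sf(z), rel=1e-9
        )

    def test_opposite_signs_cancel(self):
        per = {
            "c1": _contrast_frame([0.05], [1.0]),
            "c2": _contrast_frame([0.05], [-1.0]),
        }
        res = dp.stouffer_combine(per)
        assert res.table["combined_z"].iloc[0] == pytest.approx(0.0)
        assert res.table["combined_p"].iloc[0] == pytest.approx(1.0)
        assert not res.table["direction_consistent"].iloc[0]

    def test_single_clone_rejected(self):
        with pytest.raises(ValueError):
            dp.stouffer_combine({"c1": _contrast_frame([0.5], [1.0])})

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        frames = {
            f"c{i}": _contrast_frame(
                rng.uniform(size=10), rng.normal(size=10)
            )
            for i in range(3)
        }
        res1 = dp.stouffer_combine(frames)
        res2 = dp.stouffer_combine(dict(reversed(list(frames.items()))))
        pd.testing.assert_series_equal(
            res1.table["combined_z"], res2.table["combined_z"]
        )

    def test_identical_clones_scale_as_sqrt_k(self):
        f = _contrast_frame([0.02], [1.0])
        res = dp.stouffer_combine({"c1": f, "c2": f, "c3": f})
        z1 = sps.norm.isf(0.01)
        assert res.table["combined_z"].iloc[0] == pytest.approx(
            z1 * np.sqrt(3), rel=1e-9
        )

    def test_zero_p_capped(self):
        per = {
            "c1": _contrast_frame([0.0], [1.0]),
            "c2": _contrast_frame([0.5], [1.0]),
        }
        res = dp.stouffer_combine(per)
        assert np.isfinite(res.table["combined_z"].iloc[0])

    def test_matches_scipy_one_sided_stouffer(self):
        """Signed combination equals scipy's Stouffer on one-sided p."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = rng.integers(2, 5)
            ps = rng.uniform(1e-6, 1, size=k)
            fcs = rng.normal(size=k)
            per = {
                f"c{i}": _contrast_frame([ps[i]], [fcs[i]])
                for i in range(k)
            }
            res = dp.stouffer_combine(per)
            one_sided = np.where(fcs > 0, ps / 2, 1 - ps / 2)
            ref = sps.combine_pvalues(one_sided, method="stouffer")
            assert res.table["combined_z"].iloc[0] == pytest.approx(
                ref.statistic, rel=1e-9, abs=1e-12
            )


class TestConsensusDeps:
    def _consensus(self, ps_by_clone, fcs_by_clone):
        per = {
            c: _contrast_frame(ps_by_clone[c], fcs_by_clone[c])
            for c in ps_by_clone
        }
        return dp.stouffer_combine(per)

    def test_partial_clone_support_excluded(self):
        cons = self._consensus(
            {"c1": [0.001], "c2": [0.001], "c3": [0.5]},
            {"c1": [1.0], "c2": [1.0], "c3": [1.0]},
        )
        deps = dp.consensus_deps(cons)
        assert not deps.up and not deps.down

    def test_inconsistent_direction_excluded(self):
        cons = self._consensus(
            {"c1": [1e-6], "c2": [1e-6], "c3": [1e-6]},
            {"c1": [0.8], "c2": [0.9], "c3": [-0.7]},
        )
        deps = dp.consensus_deps(cons)
        assert not deps.up and not deps.down

    def test_consistent_feature_called_with_direction(self):
        cons = self._consensus(
            {"c1": [1e-6], "c2": [1e-6], "c3": [1e-6]},
            {"c1": [-0.8], "c2": [-0.9], "c3": [-0.7]},
        )
        deps = dp.consensus_deps(cons)
        assert deps.down == frozenset({"F0"})

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        n = 300
        ps = {c: rng.uniform(size=n) ** 2 for c in ("c1", "c2", "c3")}
        fcs = {c: rng.normal(0, 1, size=n) for c in ("c1", "c2", "c3")}
        cons = self._consensus(ps, fcs)
        loose = dp.consensus_deps(cons, p_max=0.1, lfc_min=0.3, q_max=0.1)
        tight = dp.consensus_deps(cons, p_max=0.05, lfc_min=0.5,
                                  q_max=0.005)
        assert tight.down <= loose.down
        assert tight.up <= loose.up


class TestExtractSignatures:
    def test_gene_collapse(self):
        deps = dp.DEPSets(down=frozenset({"P1", "P2"}), up=frozenset())
        induced, repressed = dp.extract_signatures(
            deps, {"P1": "GENEA", "P2": "GENEA"}
        )
        assert induced.genes == frozenset({"GENEA"})
        assert repressed.genes == frozenset()

    def test_empty_input(self):
        induced, repressed = dp.extract_signatures(
            dp.DEPSets(down=frozenset(), up=frozenset()), {}
        )
        assert not induced.genes and not repressed.genes

    def test_multi_gene_protein_group(self):
        deps = dp.DEPSets(down=frozenset({"P1"}), up=frozenset())
        induced, _ = dp.extract_signatures(
            deps, {"P1": ["GENEA", "GENEB"]}
        )
        assert induced.genes == frozenset({"GENEA", "GENEB"})


class TestNullCalibration:
    def test_welch_p_uniform_under_null(self):
        """On a null proteome with enough replicates for the
        t-approximation to be accurate, the p<0.05 rate stays in
        binomial 99% bounds around 5%."""
        qm, truth = sd.simulate_proteome(
            sd.SimParams(seed=0, frac_de=0.0, n_replicates=8,
                         n_tech_runs=1)
        )
        logged, testable = dp.prepare_matrix(qm, 3)
        res = dp.welch_contrast(
            logged, "ko1", "ctrl", features=logged.data.index[testable]
        )
        n = res["p"].notna().sum()
        rate = (res["p"] < 0.05).mean()
        lo = sps.binom.ppf(0.005, n, 0.05) / n
        hi = sps.binom.ppf(0.995, n, 0.05) / n
        assert lo <= rate <= hi

    def test_welch_never_anticonservative_at_three_replicates(self):
        """At the study's 3 replicates per group, the Welch-Satterthwaite
        approximation errs on the conservative side: the null rejection
        rate must not exceed the nominal 5% (upper binomial bound)."""
        qm, truth = sd.simulate_proteome(
            sd.SimParams(seed=0, frac_de=0.0)
        )
        qm = dp.average_technical_runs(qm, truth.extras["run_map"])
        logged, testable = dp.prepare_matrix(qm, 3)
        res = dp.welch_contrast(
            logged, "ko1", "ctrl", features=logged.data.index[testable]
        )
        n = res["p"].notna().sum()
        rate = (res["p"] < 0.05).mean()
        assert rate <= sps.binom.ppf(0.995, n, 0.05) / n

    def test_null_consensus_near_empty(self):
        qm, truth = sd.simulate_proteome(
            sd.SimParams(seed=1, frac_de=0.0)
        )
        qm = dp.average_technical_runs(qm, truth.extras["run_map"])
        logged, testable = dp.prepare_matrix(qm, 3)
        per = {
            c: dp.welch_contrast(
                logged, c, "ctrl", features=logged.data.index[testable]
            )
            for c in ("ko1", "ko2", "ko3")
        }
        deps = dp.consensus_deps(dp.stouffer_combine(per))
        assert len(deps.down | deps.up) <= max(
            1, int(0.005 * testable.sum())
        )
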