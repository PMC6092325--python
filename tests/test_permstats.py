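"""Distance matrices, PERMANOVA against classical/enumeration oracles, SIMPER."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

from jellytroph.permstats import distance_matrix, permanova, simper


class TestDistanceMatrix:
    def test_identical_rows_have_zero_distance(self):
        d = distance_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.values[0, 1] == 0.0

    def test_disjoint_support_is_maximal_bray_curtis(self):
        d = distance_matrix(np.array([[1.0, 0.0], [0.0, 2.0]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_bray_curtis(self):
        d = distance_matrix(np.array([[1.0, 2.0], [3.0, 0.0]]))
        assert d.values[0, 1] == pytest.approx(4.0 / 6.0)

    def test_negative_input_rejected_for_bray_curtis(self):
        with pytest.raises(ValueError):
            distance_matrix(np.array([[-1.0, 2.0], [3.0, 0.0]]))

    def test_all_zero_row_pair_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            d = distance_matrix(np.zeros((2, 3)))
        assert d.values[0, 1] == 0.0

    def test_log1p_transform_applied_before_metric(self):
        X = np.array([[0.0], [np.e - 1.0]])
        d = distance_matrix(X, metric="euclidean", transform="log1p")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 4))
        d = distance_matrix(X).values
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        assert np.all(d <= 1.0 + 1e-12)


def _oneway(d, groups, **kw):
    return permanova(d, pd.DataFrame({"g": groups}), ["g"], **kw)


class TestPermanovaOracles:
    def test_fixed_dataset_matches_classical_anova(self):
        d = distance_matrix(np.array([[0.0], [1.0], [2.0], [3.0]]),
                            metric="euclidean")
        res = _oneway(d, ["a", "a", "b", "b"], exhaustive=True)
        term = res.term("g")
        assert term["pseudo_F"] == pytest.approx(8.0, rel=1e-10)
        assert term["SS"] == pytest.approx(4.0, rel=1e-10)
        assert term["df"] == 1 and res.term("Residual")["df"] == 2
        assert term["p"] == pytest.approx(2.0 / 6.0, rel=1e-12)

    def test_euclidean_oneway_equals_classical_f_on_random_data(self):
        """Pseudo-F == ANOVA F to 1e-10 on 100 random univariate datasets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_per = int(rng.integers(3, 6))
            k = int(rng.integers(2, 4))
            X = rng.normal(0, 1, size=(n_per * k, 1))
            groups = np.repeat([f"g{i}" for i in range(k)], n_per)
            res = _oneway(distance_matrix(X, metric="euclidean"), groups,
                          n_perm=99, seed=0)
            expected = f_oneway(*(X[groups == g, 0] for g in set(groups))).statistic
            assert res.term("g")["pseudo_F"] == pytest.approx(expected, rel=1e-10)

    def test_monte_carlo_p_matches_enumeration(self):
        """MC p with many permutations sits within 3 MC SEs of the exact p."""
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(8, 2))
        groups = ["a"] * 4 + ["b"] * 4
        d = distance_matrix(X, metric="euclidean")
        exact = _oneway(d, groups, exhaustive=True).term("g")["p"]
        n_perm = 9999
        mc = _oneway(d, groups, n_perm=n_perm, seed=3).term("g")["p"]
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) < 3 * se + 2 / n_perm

    def test_matches_skbio_oneway_on_bray_curtis(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(9)
        X = rng.random((12, 5))
        groups = list(np.repeat(["a", "b", "c"], 4))
        d = distance_matrix(X, metric="braycurtis")
        ours = _oneway(d, groups, n_perm=99, seed=0).term("g")["pseudo_F"]
        theirs = sk_permanova(skbio.DistanceMatrix(d.values), groups,
                              permutations=99)["test statistic"]
        assert ours == pytest.approx(float(theirs), rel=1e-10)


class TestPermanovaDesigns:
    @staticmethod
    def _balanced_design(n_rep=2, three_way=False):
        rng = np.random.default_rng(17)
        levels = [("May", "Jun"), ("f", "m")] + ([("gonad", "soma")] if three_way else [])
        rows = [dict(zip(("month", "sex", "tissue"), combo))
                for combo in itertools.product(*levels)
                for _ in range(n_rep)]
        design = pd.DataFrame(rows)
        X = rng.random((len(design), 4)) + 1.0
        return X, design

    def test_two_way_ss_decomposition_is_exact(self):
        X, design = self._balanced_design()
        res = permanova(distance_matrix(X, metric="euclidean"),
                        design[["month", "sex"]], ["month", "sex"],
                        n_perm=99, seed=0)
        tab = res.table.set_index("term")
        terms = ["month", "sex", "month*sex", "Residual"]
        assert tab.loc[terms, "SS"].sum() == pytest.approx(
            tab.loc["Total", "SS"], rel=1e-6)
        assert tab.loc[terms, "df"].sum() == tab.loc["Total", "df"]

    def test_three_way_has_all_interaction_terms(self):
        X, design = self._balanced_design(three_way=True)
        res = permanova(distance_matrix(X, metric="braycurtis", transform="log1p"),
                        design, ["month", "sex", "tissue"], n_perm=99, seed=0)
        assert set(res.table["term"]) >= {
            "month", "sex", "tissue", "month*sex", "month*tissue",
            "sex*tissue", "month*sex*tissue", "Residual", "Total"}

    def test_unbalanced_multiway_rejected(self):
        X, design = self._balanced_design()
        with pytest.raises(ValueError, match="unbalanced"):
            permanova(distance_matrix(X[:-1], metric="euclidean"),
                      design.iloc[:-1][["month", "sex"]], ["month", "sex"],
                      n_perm=99)

    def test_too_few_permutations_rejected(self):
        X, design = self._balanced_design()
        with pytest.raises(ValueError, match="99"):
            permanova(distance_matrix(X, metric="euclidean"),
                      design[["month"]], ["month"], n_perm=10)

    def test_identical_samples_flagged_degenerate(self):
        X = np.ones((6, 3))
        res = _oneway(distance_matrix(X, metric="euclidean"),
                      ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.degenerate
        assert res.term("Total")["SS"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.term("g")["pseudo_F"])

    def test_null_rejection_rate_near_alpha(self):
        """Randomized labels reject at ~5% (moderate simulation)."""
        rng = np.random.default_rng(100)
        rejections = 0
        n_sim = 200
        X = rng.random((12, 3))
        d = distance_matrix(X, metric="euclidean")
        for i in range(n_sim):
            groups = rng.permutation(np.repeat(["a", "b", "c"], 4))
            res = _oneway(d, groups, n_perm=199, seed=i)
            rejections += res.term("g")["p"] <= 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.04)


class TestSimper:
    def test_single_variable_contributes_everything(self):
        out = simper(np.array([[1.0], [2.0], [3.0], [4.0]]),
                     ["a", "a", "b", "b"])
        tab = out[("a", "b")].table
        assert tab.iloc[0]["pct"] == pytest.approx(100.0)

    def test_constant_variable_contributes_nothing(self):
        X = np.array([[1.0, 5.0], [1.1, 5.0], [4.0, 5.0], [3.9, 5.0]])
        out = simper(X, ["a", "a", "b", "b"], variables=["v1", "v2"])
        tab = out[("a", "b")].table.set_index("variable")
        assert tab.loc["v1", "pct"] == pytest.approx(100.0)
        assert tab.loc["v2", "pct"] == pytest.approx(0.0)

    def test_hand_computed_pair(self):
        out = simper(np.array([[1.0, 1.0], [3.0, 1.0]]), ["A", "B"],
                     variables=["v1", "v2"])
        res = out[("A", "B")]
        assert res.overall_dissimilarity == pytest.approx(2.0 / 6.0)
        tab = res.table.set_index("variable")
        assert tab.loc["v1", "average_contribution"] == pytest.approx(2.0 / 6.0)
        assert tab.loc["v2", "average_contribution"] == 0.0

    def test_contributions_sum_to_average_dissimilarity(self):
        rng = np.random.default_rng(2)
        X = rng.random((9, 6))
        groups = np.repeat(["a", "b", "c"], 3)
        out = simper(X, groups)
        for (ga, gb), res in out.items():
            A, B = X[groups == ga], X[groups == gb]
            dis = [np.abs(x - y).sum() / (x + y).sum() for x in A for y in B]
            assert res.overall_dissimilarity == pytest.approx(np.mean(dis), rel=1e-12)
            assert res.table["average_contribution"].sum() == pytest.approx(
                res.overall_dissimilarity, rel=1e-12)
            assert res.table["pct"].sum() == pytest.approx(100.0, abs=1e-6)
            assert (res.table["cum_pct"].diff().dropna() >= -1e-9).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            simper(np.random.default_rng(0).random((4, 2)), ["a"] * 4)
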