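"""Dissimilarities, Mantel test, rank-based test battery, accumulation curves.

Hand calculations are frozen from direct evaluation of the definitions;
library oracles (scikit-bio, pingouin, scipy) provide independent
cross-checks of the authored implementations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp_st

from edna_assemblage import stats as st


class TestMorisitaHorn:
    def test_identity_zero(self):
        assert st.morisita_horn([2, 3, 1], [2, 3, 1]) == pytest.approx(0.0)

    def test_disjoint_one(self):
        assert st.morisita_horn([1, 0, 2], [0, 3, 0]) == pytest.approx(1.0)

    def test_hand_value_one_third(self):
        # x=(1,1), y=(1,0): lx=2/4, ly=1, sim = 2*1/((0.5+1)*2*1) = 2/3
        assert st.morisita_horn([1, 1], [1, 0]) == pytest.approx(1 / 3)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            st.morisita_horn([0, 0], [1, 2])

    @given(
        x=hyp_st.lists(hyp_st.integers(0, 50), min_size=3, max_size=8),
        c=hyp_st.floats(0.1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, x, c):
        y = [3, 0, 7] + [1] * (len(x) - 3)
        if sum(x) == 0:
            return
        d1 = st.morisita_horn(x, y)
        d2 = st.morisita_horn(np.array(x) * c, y)
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestJaccard:
    def test_examples(self):
        assert st.jaccard_binary([1, 1, 0], [1, 1, 0]) == 0.0
        assert st.jaccard_binary([1, 0], [0, 1]) == 1.0
        # {A,B} vs {B,C}: 1 - 1/3
        assert st.jaccard_binary([1, 1, 0], [0, 1, 1]) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            st.jaccard_binary([0, 0], [0, 0])

    def test_duplicating_shared_column_invariant(self):
        a, b = [1, 1, 0], [0, 1, 1]
        a2, b2 = a + [1], b + [1]  # duplicate the shared species
        assert st.jaccard_binary(a, b) != st.jaccard_binary(a2, b2)
        # duplicating keeps bounds and direction: shared/union both grow by 1
        assert st.jaccard_binary(a2, b2) == pytest.approx(1 - 2 / 4)


class TestPairwise:
    def test_single_unit(self):
        m = pd.DataFrame([[1, 2, 3]], index=["u"])
        d = st.pairwise(m, "morisita-horn")
        assert d.values.shape == (1, 1) and d.values.iloc[0, 0] == 0.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 20, size=(8, 5)).astype(float))
        m.iloc[:, 0] += 1  # avoid zero rows
        for metric, fn in (("morisita-horn", st.morisita_horn),
                           ("jaccard", st.jaccard_binary)):
            d = st.pairwise(m, metric)
            for i in range(8):
                for j in range(8):
                    expected = 0.0 if i == j else fn(m.iloc[i], m.iloc[j])
                    assert d.values.iloc[i, j] == pytest.approx(expected)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.integers(1, 9, size=(5, 4)),
                         index=list("abcde")).astype(float)
        d1 = st.pairwise(m, "jaccard")
        perm = ["c", "a", "e", "b", "d"]
        d2 = st.pairwise(m.loc[perm], "jaccard")
        pd.testing.assert_frame_equal(d2.values, d1.values.loc[perm, perm])


def _dist(rng, n):
    p = rng.random((n, 3))
    from scipy.spatial.distance import cdist

    d = cdist(p, p) / 3.0
    return st.DissimilarityMatrix(values=pd.DataFrame(d), metric="jaccard")


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _dist(np.random.default_rng(0), 8)
        res = st.mantel(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p >= 1 / 100

    def test_affine_invariance(self):
        d1 = _dist(np.random.default_rng(1), 8)
        v = 0.1 + 0.5 * d1.values.to_numpy()
        np.fill_diagonal(v, 0.0)
        d2 = st.DissimilarityMatrix(values=pd.DataFrame(v), metric="jaccard")
        assert st.mantel(d1, d2, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_matches_skbio_r(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        rng = np.random.default_rng(5)
        d1, d2 = _dist(rng, 9), _dist(rng, 9)
        res = st.mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = sk_mantel(
            DistanceMatrix(d1.values.to_numpy()),
            DistanceMatrix(d2.values.to_numpy()),
            permutations=0,
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_p_lower_bound_and_seed_stability(self):
        rng = np.random.default_rng(6)
        d1, d2 = _dist(rng, 7), _dist(rng, 7)
        res = st.mantel(d1, d2, n_perm=99, seed=42)
        assert res.p >= 1 / 100
        assert st.mantel(d1, d2, n_perm=99, seed=42).p == res.p

    def test_zero_variance_rejected(self):
        v = np.ones((4, 4)) - np.eye(4)
        d = st.DissimilarityMatrix(values=pd.DataFrame(v), metric="jaccard")
        with pytest.raises(ValueError, match="variance"):
            st.mantel(d, d, n_perm=9, seed=0)


class TestKruskalWallis:
    def test_hand_value_7_2(self):
        # 12/(9*10) * (6^2/3 + 15^2/3 + 24^2/3) - 3*10 = 7.2
        res = st.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == 2

    def test_within_group_order_invariant(self):
        a = st.kruskal_wallis([[3, 1, 2], [6, 4, 5]])
        b = st.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            st.kruskal_wallis([[1, 1], [1, 1]])


class TestWelchAnovaRanks:
    def test_two_groups_equals_welch_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 3, 8)
        res = st.welch_anova_ranks([a, b])
        from scipy.stats import rankdata, ttest_ind

        ranks = rankdata(np.concatenate([a, b]))
        t = ttest_ind(ranks[:12], ranks[12:], equal_var=False)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_matches_pingouin_on_ranks(self):
        import pingouin as pg
        from scipy.stats import rankdata

        rng = np.random.default_rng(8)
        groups = [rng.normal(i, 1 + i, 10 + 3 * i) for i in range(3)]
        res = st.welch_anova_ranks(groups)
        ranks = rankdata(np.concatenate(groups))
        labels = np.repeat(
            np.arange(3), [len(g) for g in groups]
        )
        df = pd.DataFrame({"y": ranks, "g": labels})
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_strong_shift_is_significant(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(0, 1, 20), rng.normal(5, 2, 20), rng.normal(10, 4, 20)]
        assert st.welch_anova_ranks(groups).p < 0.001

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError):
            st.welch_anova_ranks([[1, 1, 1], [2, 3, 4]])


class TestGamesHowellRanks:
    def test_identical_groups_t_zero_p_one(self):
        res = st.games_howell_ranks([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert res[0].statistic == pytest.approx(0.0)
        assert res[0].p == pytest.approx(1.0)

    def test_k2_equals_two_sided_welch_t_on_ranks(self):
        from scipy.stats import rankdata, ttest_ind

        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 2, 9)
        res = st.games_howell_ranks([a, b])[0]
        ranks = rankdata(np.concatenate([a, b]))
        ref = ttest_ind(ranks[:15], ranks[15:], equal_var=False)
        # q = t*sqrt(2) with k=2 reduces the studentized range to |t|
        assert res.statistic == pytest.approx(abs(ref.statistic), rel=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_pingouin_three_groups(self):
        import pingouin as pg
        from scipy.stats import rankdata

        rng = np.random.default_rng(11)
        groups = [rng.normal(i * 2, 1 + i, 12) for i in range(3)]
        res = st.games_howell_ranks(groups)
        ranks = rankdata(np.concatenate(groups))
        df = pd.DataFrame(
            {"y": ranks, "g": np.repeat(np.arange(3), [12, 12, 12])}
        )
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for row, mine in zip(ref.itertuples(), res):
            assert mine.statistic == pytest.approx(abs(row.T), abs=1e-6)
            assert mine.df == pytest.approx(row.df, rel=1e-9)
            assert mine.p == pytest.approx(row.pval, abs=1e-6)

    def test_label_permutation_permutes_pairs(self):
        rng = np.random.default_rng(12)
        g = {lab: rng.normal(i, 1, 8) for i, lab in enumerate("abc")}
        res = st.games_howell_ranks(g)
        swapped = {"c": g["c"], "b": g["b"], "a": g["a"]}
        res2 = st.games_howell_ranks(swapped)
        by_pair = {frozenset(r.groups): r.statistic for r in res}
        by_pair2 = {frozenset(r.groups): r.statistic for r in res2}
        for k in by_pair:
            assert by_pair[k] == pytest.approx(by_pair2[k])


class TestSelectDepthTest:
    def test_heteroscedastic_routes_to_welch(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(0, 1, 30), rng.normal(0.5, 10, 30), rng.normal(1, 10, 30)]
        dec = st.select_depth_test(groups)
        assert dec.chosen == "welch-anova-ranks"
        assert dec.levene_p <= 0.05

    def test_homoscedastic_nonnormal_routes_to_kruskal(self):
        rng = np.random.default_rng(14)
        groups = [rng.exponential(1, 40), rng.exponential(1, 40) + 0.2,
                  rng.exponential(1, 40)]
        dec = st.select_depth_test(groups)
        assert dec.chosen == "kruskal-wallis"

    def test_normal_homoscedastic_still_rank_based_with_note(self):
        rng = np.random.default_rng(15)
        groups = [rng.normal(0, 1, 40), rng.normal(0, 1, 40)]
        dec = st.select_depth_test(groups)
        assert dec.chosen == "kruskal-wallis"
        assert any("rank-based" in n for n in dec.notes)

    def test_posthoc_only_when_welch_significant(self):
        rng = np.random.default_rng(16)
        groups = [rng.normal(0, 1, 30), rng.normal(6, 8, 30), rng.normal(12, 15, 30)]
        dec = st.select_depth_test(groups)
        assert dec.chosen == "welch-anova-ranks"
        assert dec.posthoc is not None and len(dec.posthoc) == 3


class TestSpeciesAccumulation:
    def test_endpoint_and_first_point_identities(self):
        rng = np.random.default_rng(17)
        x = rng.random((6, 10)) < 0.4
        x[:, 0] = True
        curve = st.species_accumulation(x, n_perm=50, seed=0)
        assert curve.mean_richness[-1] == pytest.approx(x.any(axis=0).sum())
        # E[richness at n=1] = mean per-sample richness
        assert curve.mean_richness[0] == pytest.approx(
            x.sum(axis=1).mean(), abs=1.0
        )
        assert (np.diff(curve.mean_richness) >= -1e-12).all()

    def test_matches_exhaustive_enumeration_n5(self):
        rng = np.random.default_rng(18)
        x = rng.random((5, 4)) < 0.5
        x[0, 0] = True
        exact = np.zeros(5)
        perms = list(itertools.permutations(range(5)))
        for order in perms:
            seen = np.logical_or.accumulate(x[list(order)], axis=0)
            exact += seen.sum(axis=1)
        exact /= len(perms)
        # with every permutation sampled many times the mean converges; use
        # the exact mean over a full enumeration via big n_perm on tiny n
        curve = st.species_accumulation(x, n_perm=20000, seed=1)
        np.testing.assert_allclose(curve.mean_richness, exact, atol=0.05)
        # and the deterministic endpoints agree exactly
        assert curve.mean_richness[-1] == pytest.approx(exact[-1], abs=1e-12)
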