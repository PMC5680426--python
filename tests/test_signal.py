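import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evotox import (
    aggregate_species,
    blomberg_k,
    bm_profile_loglik,
    duration_effect_test,
    estimate_lambda,
    grafen_branch_lengths,
    lambda_transform,
    mantel_test,
    parse_newick,
    patristic_distances,
    permutation_test_k,
    phylo_vcv,
    run_signal_suite,
    trait_distance_matrix,
)
from evotox.signal import lambda_max
from evotox.simulate import simulate_bm_traits, simulate_trait_dataset, simulate_yule_tree
from evotox.tree import DistanceMatrix


def _records(rows):
    return pd.DataFrame(
        rows, columns=["species", "study", "lc50_mg_l", "duration_h", "phylum", "class", "group"]
    )


class TestAggregation:
    def test_within_study_then_across_study_means(self):
        recs = _records(
            [
                ("sp1", "s1", 1000.0, 96, "P", "C", "G"),
                ("sp1", "s1", 2000.0, 96, "P", "C", "G"),
            ]
        )
        assert aggregate_species(recs)["sp1"] == pytest.approx(1500.0)
        recs2 = _records(
            [
                ("sp1", "s1", 500.0, 96, "P", "C", "G"),
                ("sp1", "s1", 1500.0, 96, "P", "C", "G"),  # study mean 1000
                ("sp1", "s2", 3000.0, 48, "P", "C", "G"),  # study mean 3000
            ]
        )
        assert aggregate_species(recs2)["sp1"] == pytest.approx(2000.0)

    def test_single_record_identity(self):
        recs = _records([("sp1", "s1", 4395.0, 96, "P", "C", "G")])
        assert aggregate_species(recs)["sp1"] == pytest.approx(4395.0)

    def test_nonpositive_lc50_rejected(self):
        recs = _records([("sp1", "s1", -2.0, 96, "P", "C", "G")])
        with pytest.raises(ValueError, match="sp1"):
            aggregate_species(recs)


class TestDurationTest:
    def test_identical_groups_give_zero_f(self):
        recs = _records(
            [("a", "s", 1.0, 48, "P", "C", "G"), ("b", "s", 1.0, 48, "P", "C", "G"),
             ("c", "s", 1.0, 96, "P", "C", "G"), ("d", "s", 1.0, 96, "P", "C", "G")]
        )
        res = duration_effect_test(recs)
        assert res.f_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_equal_group_means_give_zero_f(self):
        rows = [(f"x{i}", "s", v, d, "P", "C", "G")
                for i, (v, d) in enumerate([(1, 48), (2, 48), (3, 48), (1, 96), (2, 96), (3, 96)])]
        assert duration_effect_test(_records(rows)).f_stat == 0.0

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(10, 2, 8), rng.normal(12, 2, 11)
        rows = [(f"a{i}", "s", v, 48, "P", "C", "G") for i, v in enumerate(a)]
        rows += [(f"b{i}", "s", v, 96, "P", "C", "G") for i, v in enumerate(b)]
        res = duration_effect_test(_records(rows))
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)
        assert res.df == (1, 17)

    def test_single_group_errors(self):
        recs = _records([("a", "s", 1.0, 96, "P", "C", "G"), ("b", "s", 2.0, 96, "P", "C", "G")])
        with pytest.raises(ValueError):
            duration_effect_test(recs)


class TestLambdaTransform:
    def test_identity_zero_and_half(self, balanced4):
        c = phylo_vcv(balanced4)
        np.testing.assert_allclose(lambda_transform(c, 1.0).matrix, c.matrix)
        np.testing.assert_allclose(lambda_transform(c, 0.0).matrix, np.eye(4), atol=1e-12)
        half = lambda_transform(c, 0.5).matrix
        off = half[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off[off > 0], 1 / 3)

    def test_infeasible_lambda_rejected(self, balanced4):
        c = phylo_vcv(balanced4)
        with pytest.raises(ValueError):
            lambda_transform(c, lambda_max(c) + 0.1)
        with pytest.raises(ValueError):
            lambda_transform(c, -0.2)


class TestBmLoglik:
    def test_identity_covariance_reduces_to_ols(self, star_tree):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0, 2.5, 1.5])
        ll, mu, s2 = bm_profile_loglik(x, phylo_vcv(star_tree))
        assert mu == pytest.approx(x.mean())
        assert s2 == pytest.approx(np.mean((x - x.mean()) ** 2))

    def test_matches_mvn_density_oracle(self, balanced4):
        x = np.array([0.2, -0.4, 1.1, 0.9])
        c = phylo_vcv(balanced4)
        ll, mu, s2 = bm_profile_loglik(x, c)
        oracle = sps.multivariate_normal.logpdf(x, mean=np.full(4, mu), cov=s2 * c.matrix)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_location_invariance(self, balanced4):
        x = np.array([0.2, -0.4, 1.1, 0.9])
        c = phylo_vcv(balanced4)
        ll1, mu1, s21 = bm_profile_loglik(x, c)
        ll2, mu2, s22 = bm_profile_loglik(x + 7.5, c)
        assert mu2 == pytest.approx(mu1 + 7.5)
        assert s22 == pytest.approx(s21)
        assert ll2 == pytest.approx(ll1)

    def test_constant_trait_rejected(self, balanced4):
        with pytest.raises(ValueError):
            bm_profile_loglik(np.ones(4), phylo_vcv(balanced4))


class TestEstimateLambda:
    def test_optimum_beats_grid(self):
        tree = simulate_yule_tree(40, seed=3)
        x = simulate_bm_traits(tree, lambda_true=0.6, seed=3)
        res = estimate_lambda(x, tree)
        c = phylo_vcv(tree)
        grid_best = max(
            bm_profile_loglik(x.loc[list(tree.tip_labels)].to_numpy(), lambda_transform(c, g))[0]
            for g in np.linspace(0, 1, 101)
        )
        assert res.loglik >= grid_best - 1e-6

    def test_permuted_traits_lose_signal(self):
        tree = grafen_branch_lengths(simulate_yule_tree(64, seed=9))
        x = simulate_bm_traits(tree, lambda_true=1.0, seed=9)
        rng = np.random.default_rng(0)
        hats = []
        for _ in range(10):
            shuffled = pd.Series(rng.permutation(x.to_numpy()), index=x.index)
            hats.append(estimate_lambda(shuffled, tree).lambda_hat)
        assert np.mean(hats) < 0.25

    def test_needs_four_species(self):
        with pytest.raises(ValueError):
            estimate_lambda(np.array([1.0, 2.0]), parse_newick("(A:1,B:1);"))


class TestBlombergK:
    def test_star_identity_exact(self, star_tree):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=8)
            assert blomberg_k(x, star_tree) == pytest.approx(1.0, abs=1e-10)

    def test_four_tip_dense_matrix_oracle(self, balanced4):
        x = np.array([0.0, 0.0, 1.0, 1.0])  # aligned to tips A,B,C,D
        c = phylo_vcv(balanced4).matrix
        ci = np.linalg.inv(c)
        one = np.ones(4)
        mu = one @ ci @ x / (one @ ci @ one)
        r = x - mu
        mse0 = r @ r / 3
        mse = r @ ci @ r / 3
        expected_ratio = (np.trace(c) - 4 / (one @ ci @ one)) / 3
        oracle = (mse0 / mse) / expected_ratio
        assert blomberg_k(x, balanced4) == pytest.approx(oracle, rel=1e-12)

    def test_mean_k_near_one_under_bm(self):
        ks = []
        for s in range(60):
            t = simulate_yule_tree(40, seed=s)
            ks.append(blomberg_k(simulate_bm_traits(t, seed=s), t))
        assert 0.8 < np.mean(ks) < 1.2


class TestPermutationK:
    def test_deterministic_given_seed(self, balanced4):
        x = np.array([0.1, 0.3, 1.4, 1.2])
        a = permutation_test_k(x, balanced4, n_perm=199, seed=42)
        b = permutation_test_k(x, balanced4, n_perm=199, seed=42)
        assert a == b

    def test_clustered_trait_rejects(self):
        tree = grafen_branch_lengths(parse_newick(
            "((a1,(a2,(a3,(a4,(a5,(a6,(a7,(a8,(a9,a10))))))))),"
            "(b1,(b2,(b3,(b4,(b5,(b6,(b7,(b8,(b9,b10))))))))));"
        ))
        x = pd.Series(
            [0.0] * 10 + [1.0] * 10,
            index=[f"a{i}" for i in range(1, 11)] + [f"b{i}" for i in range(1, 11)],
        )
        res = permutation_test_k(x, tree, n_perm=999, seed=7)
        assert res.p_value <= 0.01

    def test_exchangeable_null_calibration(self):
        # iid traits are exchangeable across tips, so the randomization test
        # is exact and rejections at alpha should occur at rate ~alpha.
        # (an exact star tree cannot serve here: with C = I the permutation
        # statistic is invariant, so the test is degenerate by construction)
        tree = simulate_yule_tree(16, seed=77)
        rng = np.random.default_rng(123)
        rej = 0
        n_sim = 200
        for i in range(n_sim):
            x = rng.normal(size=16)
            if permutation_test_k(x, tree, n_perm=99, seed=i).p_value <= 0.05 + 1e-12:
                rej += 1
        assert 0.01 <= rej / n_sim <= 0.12

    def test_star_tree_p_is_degenerate(self, star_tree):
        # permutation invariance of the statistic on a star: p must be 1
        x = np.random.default_rng(5).normal(size=8)
        assert permutation_test_k(x, star_tree, n_perm=99, seed=0).p_value == pytest.approx(1.0)

    def test_minimum_permutations_enforced(self, balanced4):
        with pytest.raises(ValueError):
            permutation_test_k(np.arange(4.0), balanced4, n_perm=10)


class TestMantel:
    def test_perfect_and_affine_correlation(self):
        t = simulate_yule_tree(10, seed=4)
        d1 = patristic_distances(t)
        r1 = mantel_test(d1, d1, n_perm=99, seed=0)
        assert r1.r == pytest.approx(1.0)
        scaled = DistanceMatrix(d1.labels, 3.0 * d1.values)
        assert mantel_test(d1, scaled, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_label_mismatch_and_zero_variance(self):
        t = simulate_yule_tree(6, seed=1)
        d1 = patristic_distances(t)
        flipped = DistanceMatrix(tuple(reversed(d1.labels)), d1.values)
        with pytest.raises(ValueError):
            mantel_test(d1, flipped)
        zero = DistanceMatrix(d1.labels, np.zeros_like(d1.values))
        with pytest.raises(ValueError):
            mantel_test(d1, zero)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        labels = ("a", "b", "c", "d", "e")
        rng = np.random.default_rng(8)
        pts1, pts2 = rng.normal(size=5), rng.normal(size=5)
        m1 = np.abs(pts1[:, None] - pts1[None, :])
        m2 = np.abs(pts2[:, None] - pts2[None, :])
        d1, d2 = DistanceMatrix(labels, m1), DistanceMatrix(labels, m2)
        iu = np.triu_indices(5, 1)
        r_obs = np.corrcoef(m1[iu], m2[iu])[0, 1]
        count = sum(
            np.corrcoef(m1[iu], m2[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12
            for p in itertools.permutations(range(5))
        )
        exact_p = count / 120  # exceedance probability incl. identity
        res = mantel_test(d1, d2, n_perm=4999, seed=3)
        mc_sd = np.sqrt(exact_p * (1 - exact_p) / 4999)
        assert abs(res.p_value - exact_p) <= 3 * mc_sd + 2 / 4999

    def test_cross_check_against_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        t = simulate_yule_tree(12, seed=6)
        x = simulate_bm_traits(t, seed=6)
        d1 = patristic_distances(t)
        d2 = trait_distance_matrix(x.loc[list(t.tip_labels)])
        ours = mantel_test(d1, d2, n_perm=999, seed=1)
        r_sk, p_sk, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, ids=d1.labels),
            skbio_distance.DistanceMatrix(d2.values, ids=d2.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert ours.r == pytest.approx(r_sk, abs=1e-10)
        assert ours.p_value == pytest.approx(p_sk, abs=0.05)


class TestTraitDistance:
    def test_examples_and_loop_oracle(self):
        d = trait_distance_matrix(pd.Series({"A": 1.0, "B": 4.0}))
        assert d.values[0, 1] == pytest.approx(3.0)
        rng = np.random.default_rng(11)
        vals = pd.Series(rng.normal(size=7), index=list("abcdefg"))
        d = trait_distance_matrix(vals)
        for i, a in enumerate(vals.index):
            for j, b in enumerate(vals.index):
                assert d.values[i, j] == pytest.approx(abs(vals[a] - vals[b]))

    def test_identical_values_zero_matrix(self):
        d = trait_distance_matrix(pd.Series({"A": 2.0, "B": 2.0, "C": 2.0}))
        assert np.all(d.values == 0)


class TestSignalSuite:
    def test_simulated_high_signal_dataset(self):
        tree, records, truth = simulate_trait_dataset(40, lambda_true=1.0, seed=21)
        values = aggregate_species(records)
        suite = run_signal_suite(
            np.log10(values).rename("lc50_mg_l"),
            tree,
            groups=[("all", list(values.index)), ("half", list(values.index[:20]))],
            n_perm=199,
            seed=5,
        )
        assert len(suite.table) == 2
        row = suite.table.set_index("group").loc["all"]
        assert row["lambda_hat"] > 0.7
        assert row["p_k"] < 0.05
        assert row["mantel_p"] < 0.05

    def test_small_group_skipped_with_no_row(self):
        tree, records, _ = simulate_trait_dataset(20, seed=3)
        values = aggregate_species(records)
        suite = run_signal_suite(
            values, tree,
            groups=[("tiny", list(values.index[:3])), ("all", list(values.index))],
            n_perm=99, seed=0,
        )
        assert suite.skipped_groups == [("tiny", 3)]
        assert list(suite.table["group"]) == ["all"]

    def test_groups_are_isolated(self):
        tree, records, _ = simulate_trait_dataset(24, seed=13)
        values = aggregate_species(records)
        g1 = list(values.index[:12])
        g2 = list(values.index[12:])
        both = run_signal_suite(values, tree, groups=[("g1", g1), ("g2", g2)], n_perm=99, seed=4)
        alone = run_signal_suite(values, tree, groups=[("g1", g1)], n_perm=99, seed=4)
        pd.testing.assert_frame_equal(
            both.table[both.table["group"] == "g1"].reset_index(drop=True), alone.table
        )

    def test_empty_group_list_errors(self):
        tree, records, _ = simulate_trait_dataset(10, seed=1)
        with pytest.raises(ValueError):
            run_signal_suite(aggregate_species(records), tree, groups=[])

    def test_species_missing_from_tree_reported(self):
        tree, records, _ = simulate_trait_dataset(12, seed=2)
        values = aggregate_species(records)
        values["ghost_species"] = 1234.0
        suite = run_signal_suite(values, tree, n_perm=99, seed=0)
        assert suite.species_not_in_tree == ["ghost_species"]
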