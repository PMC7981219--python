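"""Closed-form GLS checks, likelihood nesting, recovery, and MPD/SES behavior."""
import numpy as np
import pytest

from sympatria.phylo_comparative import (
    _eb_corr,
    _ou_corr,
    _profile_gls,
    ancestral_states_bm,
    bm_fit,
    correlate,
    eb_fit,
    mpd,
    mpd_ses,
    ou_fit,
    pagels_lambda,
    pgls_residuals,
)
from sympatria.synthetic_data import simulate_bm_trait, simulate_yule_tree
from sympatria.trees import Phylogeny
from sympatria.utils import ValidationError


class TestBMClosedForms:
    def test_two_tip_root_is_mean_sigma2_is_d2_over_4t(self, cherry):
        fit = bm_fit(cherry, {"A": 0.0, "B": 2.0})
        assert fit.root_state == pytest.approx(1.0, abs=1e-12)
        # sigma2_ML = (x1-x2)^2 / (4 t) for a 2-tip star with branch length t
        assert fit.sigma2 == pytest.approx(4.0 / 4.0, abs=1e-12)

    def test_all_equal_traits_degenerate(self, cherry):
        fit = bm_fit(cherry, {"A": 5.0, "B": 5.0})
        assert fit.sigma2 == 0.0

    def test_missing_tip_listed(self, three_tip):
        with pytest.raises(ValidationError, match="C"):
            bm_fit(three_tip, {"A": 1.0, "B": 2.0})

    def test_sigma2_recovery_within_replicate_interval(self):
        # BM data on a 200-tip tree: the closed-form ML estimate is unbiased
        tree = simulate_yule_tree(200, 1.0, seed=10)
        true = 8.0
        ests = [bm_fit(tree, simulate_bm_trait(tree, 76.0, true, seed=s)).sigma2
                for s in range(200)]
        lo, hi = np.quantile(ests, [0.025, 0.975])
        assert lo <= true <= hi
        assert np.mean(ests) == pytest.approx(true, rel=0.05)


class TestNesting:
    @pytest.fixture
    def setup(self):
        tree = simulate_yule_tree(40, 1.0, seed=21)
        traits = simulate_bm_trait(tree, 76.0, 8.0, seed=22)
        x = tree.trait_vector(traits.svl_mm)
        return tree, traits, x

    def test_ou_alpha_zero_equals_bm(self, setup):
        tree, traits, x = setup
        C, T = tree.vcv(), tree.depth()
        bm = bm_fit(tree, traits)
        assert _profile_gls(_ou_corr(C, T, 0.0), x)[2] == pytest.approx(
            bm.log_likelihood, abs=1e-6)
        # and continuity just above zero
        assert _profile_gls(_ou_corr(C, T, 1e-9), x)[2] == pytest.approx(
            bm.log_likelihood, abs=1e-4)

    def test_eb_r_zero_equals_bm(self, setup):
        tree, traits, x = setup
        bm = bm_fit(tree, traits)
        assert _profile_gls(_eb_corr(tree.vcv(), 0.0), x)[2] == pytest.approx(
            bm.log_likelihood, abs=1e-6)
        assert _profile_gls(_eb_corr(tree.vcv(), 1e-10), x)[2] == pytest.approx(
            bm.log_likelihood, abs=1e-4)

    def test_lambda_one_equals_bm(self, setup):
        tree, traits, _ = setup
        bm = bm_fit(tree, traits)
        lam = pagels_lambda(tree, traits)
        assert lam.log_likelihood >= bm.log_likelihood - 1e-6

    def test_fitted_ou_eb_never_below_bm(self, setup):
        tree, traits, _ = setup
        bm = bm_fit(tree, traits)
        assert ou_fit(tree, traits).log_likelihood >= bm.log_likelihood - 1e-4
        assert eb_fit(tree, traits).log_likelihood >= bm.log_likelihood - 1e-4

    def test_non_ultrametric_tree_rejected_for_ou(self):
        t = Phylogeny.from_newick("((A:1,B:2):1,C:4);")
        with pytest.raises(ValidationError):
            ou_fit(t, {"A": 1.0, "B": 2.0, "C": 3.0})


class TestOUEBRecovery:
    def test_ou_alpha_near_zero_on_bm_data(self):
        tree = simulate_yule_tree(100, 1.0, seed=30)
        wins = 0
        for s in range(60):
            traits = simulate_bm_trait(tree, 76.0, 8.0, seed=1000 + s)
            ou = ou_fit(tree, traits)
            bm = bm_fit(tree, traits)
            if ou.log_likelihood - bm.log_likelihood < 2.0:
                wins += 1
        assert wins >= 54  # >= 90%: OU adds nothing when BM generated the data

    def test_ou_alpha_recovered_when_large(self):
        # simulate directly under OU covariance with strong pull
        tree = simulate_yule_tree(100, 1.0, seed=31)
        T = tree.depth()
        alpha = 5.0 / T
        V = _ou_corr(tree.vcv(), T, alpha) * 8.0
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
        rng = np.random.default_rng(32)
        alphas = []
        for _ in range(20):
            x = 76.0 + L @ rng.standard_normal(len(V))
            traits = dict(zip(tree.tip_labels, x))
            alphas.append(ou_fit(tree, traits).alpha)
        assert np.quantile(alphas, 0.05) > 0.5 / T  # interval excludes zero


class TestAncestralStates:
    def test_star_tree_root_is_mean(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        anc = ancestral_states_bm(star, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0})
        assert anc.root == pytest.approx(3.0, abs=1e-9)

    def test_three_tip_matches_explicit_gls_oracle(self, three_tip):
        x = np.array([1.0, 3.0, 6.0])  # A, B, C
        C = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        Ci = np.linalg.inv(C)
        one = np.ones(3)
        mu = one @ Ci @ x / (one @ Ci @ one)
        # internal cherry node: depth 1, shares 1 with A and B, 0 with C
        cov = np.array([1.0, 1.0, 0.0])
        expected = mu + cov @ Ci @ (x - mu)
        anc = ancestral_states_bm(three_tip, dict(zip(["A", "B", "C"], x)))
        cherry_est = [v for k, v in anc.estimates.items() if k != anc.root_label]
        assert anc.root == pytest.approx(mu, abs=1e-9)
        assert cherry_est[0] == pytest.approx(expected, abs=1e-9)

    def test_constant_traits_constant_states(self, three_tip):
        anc = ancestral_states_bm(three_tip, {"A": 7.0, "B": 7.0, "C": 7.0})
        assert all(v == pytest.approx(7.0, abs=1e-9) for v in anc.estimates.values())


class TestLambda:
    def test_bm_data_high_signal_shuffled_low(self):
        tree = simulate_yule_tree(200, 1.0, seed=40)
        labels = tree.tip_labels
        rng = np.random.default_rng(41)
        hi, lo = 0, 0
        reps = 40
        for s in range(reps):
            traits = simulate_bm_trait(tree, 76.0, 8.0, seed=2000 + s)
            if pagels_lambda(tree, traits).lambda_ >= 0.9:
                hi += 1
            shuffled = dict(zip(rng.permutation(labels), [traits.svl_mm[l] for l in labels]))
            if pagels_lambda(tree, shuffled).lambda_ <= 0.1:
                lo += 1
        assert hi >= 0.9 * reps
        assert lo >= 0.9 * reps

    def test_lambda_optimum_not_worse_than_endpoints(self):
        tree = simulate_yule_tree(50, 1.0, seed=42)
        traits = simulate_bm_trait(tree, 76.0, 8.0, seed=43)
        lam = pagels_lambda(tree, traits)
        x = tree.trait_vector(traits.svl_mm)
        C = tree.vcv()
        D = np.diag(np.diag(C))
        for l in (0.0, 1.0):
            assert lam.log_likelihood >= _profile_gls(l * C + (1 - l) * D, x)[2] - 1e-6


class TestPGLS:
    def test_star_tree_reduces_to_ols_residuals(self):
        star = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
        vals = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0}
        res = pgls_residuals(star, vals)
        for sp in vals:
            assert res[sp] == pytest.approx(vals[sp] - 3.0, abs=1e-9)

    def test_gls_mean_equals_bm_root(self, three_tip):
        vals = {"A": 1.0, "B": 3.0, "C": 6.0}
        fit = bm_fit(three_tip, vals)
        res = pgls_residuals(three_tip, vals)
        x = three_tip.trait_vector(vals)
        for lab, xi in zip(three_tip.tip_labels, x):
            assert res[lab] == pytest.approx(xi - fit.root_state, abs=1e-9)

    def test_weighted_residual_sum_is_zero(self):
        tree = simulate_yule_tree(30, 1.0, seed=50)
        traits = simulate_bm_trait(tree, 76.0, 8.0, seed=51)
        res = pgls_residuals(tree, traits)
        Ci = np.linalg.inv(tree.vcv())
        r = np.array([res[l] for l in tree.tip_labels])
        assert Ci.sum(axis=1) @ r == pytest.approx(0.0, abs=1e-8)


class TestMPD:
    def test_two_species_is_their_patristic_distance(self, three_tip):
        # A sits at depth 2 via the cherry, C at depth 2: path length 4
        assert mpd({"A", "C"}, three_tip) == pytest.approx(4.0)

    def test_balanced_four_hand_value(self, balanced_four):
        # pairs: AB=2, CD=2, and 4 cross pairs of 4 -> mean = (2+2+16)/6
        assert mpd({"A", "B", "C", "D"}, balanced_four) == pytest.approx(20 / 6)

    def test_duplicates_and_order_ignored(self, balanced_four):
        assert mpd(["C", "A", "A", "C"], balanced_four) == mpd({"A", "C"}, balanced_four)

    def test_below_two_species_undefined(self, balanced_four):
        assert np.isnan(mpd({"A"}, balanced_four))


class TestMPDSES:
    def test_assemblage_equal_to_pool_degenerate(self):
        tree = simulate_yule_tree(12, 1.0, seed=60)
        pool = set(tree.tip_labels)
        res, = [r for r in mpd_ses({"all": pool}, tree, n_null=99, seed=1)]
        assert res.degenerate and np.isnan(res.ses)

    def test_null_calibration(self):
        # random assemblages: p_quantile <= 0.05 in about 5% of region-tests
        tree = simulate_yule_tree(40, 1.0, seed=61)
        tips = tree.tip_labels
        rng = np.random.default_rng(62)
        n_rej = n_tot = 0
        for rep in range(300):
            assemblages = {i: set(rng.choice(tips, size=8, replace=False)) for i in range(3)}
            for r in mpd_ses(assemblages, tree, n_null=199, seed=rep):
                n_tot += 1
                n_rej += r.p_quantile <= 0.05
        assert n_rej / n_tot == pytest.approx(0.05, abs=0.02)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_clade_is_clustered(self, seed):
        tree = simulate_yule_tree(64, 1.0, seed=200 + seed)
        # deepest clade with 6-12 tips
        best = None
        for node in tree.dendropy_tree.preorder_node_iter():
            tips = [l.taxon.label for l in node.leaf_iter()]
            if 6 <= len(tips) <= 12:
                best = tips
                break
        assert best is not None
        rng = np.random.default_rng(seed)
        other = set(rng.choice([t for t in tree.tip_labels if t not in best], 20, replace=False))
        res = {r.region: r for r in mpd_ses({"clade": set(best), "rand": other}, tree,
                                            n_null=199, seed=seed)}
        assert res["clade"].ses < 0
        assert res["clade"].p_quantile <= 0.05


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        r = correlate(x, 2 * x + 1, "pearson")
        assert r.estimate == pytest.approx(1.0)
        assert r.df == 8

    def test_monotone_nonlinear_spearman_one_pearson_below(self):
        x = np.linspace(1, 3, 12)
        y = x**3
        assert correlate(x, y, "spearman").estimate == pytest.approx(1.0)
        assert correlate(x, y, "pearson").estimate < 1.0

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(63)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r = correlate(x, y, "pearson")
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r.estimate == pytest.approx(manual, abs=1e-12)
        from scipy import stats as ss

        t = manual * np.sqrt(8 / (1 - manual**2))
        assert r.p_value == pytest.approx(2 * ss.t.sf(abs(t), 8), abs=1e-12)

    def test_zero_variance_flagged(self):
        r = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not r.defined
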