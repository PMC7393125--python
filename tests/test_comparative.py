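import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylodisp.comparative import (
    bm_rate_from_contrasts,
    inverse_patristic_weights,
    lineage_rank_tests,
    morans_i,
    phyl_anova,
    pic,
    pic_correlation,
    simulate_bm,
)
from phylodisp.errors import DegenerateDataError, ValidationError
from phylodisp.trees import DatedTree

# Reference values computed with ape 5.8 in R (pic and Moran.I) on this tree.
APE_TREE = "((A:1,(B:0.5,C:0.5):0.5):2,(D:1.5,E:1.5):1.5);"
APE_TRAIT = {"A": 1.2, "B": 3.4, "C": 2.1, "D": 0.3, "E": 5.5}
APE_PIC_SORTED = [-3.0022214, -1.1716899, -0.3764612, 1.3]
APE_MORANS_I = -0.3827507


def bm_covariance(tree: DatedTree) -> pd.DataFrame:
    """Shared-path-length matrix: Cov[x_i, x_j] under unit-rate BM."""
    labels = sorted(tree.tip_labels)
    d = tree.patristic_matrix().loc[labels, labels].to_numpy()
    depth = tree.root_age
    return pd.DataFrame(depth - d / 2, index=labels, columns=labels)


class TestMoransI:
    def test_matches_brute_force_double_summation(self):
        t = DatedTree.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        w = inverse_patristic_weights(t)
        x = pd.Series({"A": 0.3, "B": 1.9, "C": -0.7, "D": 2.2})
        res = morans_i(x, t, n_perm=9, seed=0)
        labels = list(w.index)
        z = x[labels].to_numpy() - x[labels].mean()
        wn = w.to_numpy()
        num = sum(
            wn[i, j] * z[i] * z[j] for i in range(4) for j in range(4)
        )
        brute = 4 / wn.sum() * num / (z @ z)
        assert res.morans_i == pytest.approx(brute, rel=1e-12)

    def test_matches_ape_reference(self):
        t = DatedTree.from_newick(APE_TREE)
        res = morans_i(pd.Series(APE_TRAIT), t, n_perm=9, seed=0)
        assert res.morans_i == pytest.approx(APE_MORANS_I, abs=1e-6)
        assert res.expected_null == pytest.approx(-0.25)

    def test_mean_over_all_permutations_is_closed_form_null(self):
        from itertools import permutations

        t = DatedTree.from_newick("(((A:1,B:1):1,C:2):1,(D:1,E:2):1);".replace("D:1,E:2", "D:2,E:2"))
        w = inverse_patristic_weights(t).to_numpy()
        x = np.array([0.5, 1.7, -0.3, 2.9, 0.1])
        z = x - x.mean()
        n = 5
        vals = []
        for perm in permutations(range(n)):
            zp = z[list(perm)]
            vals.append(n / w.sum() * (zp @ w @ zp) / (zp @ zp))
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=1e-12)

    def test_affine_invariance_and_seed_reproducibility(self, balanced_tree):
        x = pd.Series(
            {l: v for l, v in zip(sorted(balanced_tree.tip_labels), [1, 5, 2, 8, 3, 9, 4, 7])}
        )
        a = morans_i(x, balanced_tree, n_perm=199, seed=42)
        b = morans_i(3 * x - 10, balanced_tree, n_perm=199, seed=42)
        assert a.morans_i == pytest.approx(b.morans_i, rel=1e-12)
        assert a.p_value == b.p_value

    def test_planted_clade_signal_detected(self, balanced_tree):
        # indicator of the two depth-10 clades, slightly jittered
        rng = np.random.default_rng(0)
        labels = sorted(balanced_tree.tip_labels)
        x = pd.Series(
            [1.0 if l in "ABCD" else 0.0 for l in labels], index=labels
        ) + rng.normal(0, 0.05, 8)
        res = morans_i(x, balanced_tree, n_perm=999, seed=1)
        assert res.morans_i > 0
        assert res.p_value <= 0.05

    def test_constant_trait_is_an_error(self, balanced_tree):
        x = pd.Series(1.0, index=balanced_tree.tip_labels)
        with pytest.raises(DegenerateDataError):
            morans_i(x, balanced_tree, n_perm=9, seed=0)


class TestSimulateBM:
    def test_sister_tip_covariance_closed_form(self):
        t = DatedTree.from_newick("((A:1,B:1):2,C:3);")
        sims = simulate_bm(t, rate=2.0, n_sim=10_000, seed=3)
        cov = np.cov(sims["A"], sims["B"])
        assert cov[0, 1] == pytest.approx(2.0 * 2, rel=0.05)  # shared stem = 2
        assert cov[0, 0] == pytest.approx(2.0 * 3, rel=0.05)  # total depth = 3

    def test_star_tree_gives_iid_tips(self):
        t = DatedTree.from_newick("(A:1,B:1,C:1,D:1);")
        sims = simulate_bm(t, rate=1.0, n_sim=20_000, seed=4)
        c = np.corrcoef(sims.to_numpy().T)
        off = c[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        assert sims.var().to_numpy() == pytest.approx(np.ones(4), rel=0.05)

    def test_nonpositive_rate_rejected(self, balanced_tree):
        with pytest.raises(ValidationError):
            simulate_bm(balanced_tree, rate=0.0, n_sim=1)


class TestPic:
    def test_two_tip_closed_form(self):
        t = DatedTree.from_newick("(A:1,B:1);")
        c = pic(t, pd.Series({"A": 3.0, "B": 1.0}))
        assert c == pytest.approx([2 / np.sqrt(2)])

    def test_matches_ape_reference(self):
        t = DatedTree.from_newick(APE_TREE)
        c = np.sort(pic(t, pd.Series(APE_TRAIT)))
        np.testing.assert_allclose(c, APE_PIC_SORTED, atol=1e-6)

    def test_constant_trait_gives_zero_contrasts(self, balanced_tree):
        c = pic(balanced_tree, pd.Series(2.5, index=balanced_tree.tip_labels))
        assert c.shape == (7,)
        np.testing.assert_allclose(c, 0.0)

    def test_sum_of_squares_equals_gls_quadratic_form(self):
        # Felsenstein contrasts are an orthonormal rotation of the
        # BM-whitened residuals, so sum(c^2) must equal the GLS quadratic
        # form (x - mu)' C^-1 (x - mu) with mu the GLS mean.
        rng = np.random.default_rng(8)
        for nwk in [
            "((A:1,(B:0.5,C:0.5):0.5):2,(D:1.5,E:1.5):1.5);",
            "(((A:1,B:1):1,C:2):3,(D:4,E:4):1);",
        ]:
            t = DatedTree.from_newick(nwk)
            labels = sorted(t.tip_labels)
            x = pd.Series(rng.normal(size=5), index=labels)
            c = pic(t, x)
            cov = bm_covariance(t).to_numpy()
            cinv = np.linalg.inv(cov)
            one = np.ones(5)
            mu = (one @ cinv @ x[labels].to_numpy()) / (one @ cinv @ one)
            resid = x[labels].to_numpy() - mu
            assert float(c @ c) == pytest.approx(float(resid @ cinv @ resid), rel=1e-9)

    def test_zero_length_sister_pair_raises(self):
        t = DatedTree.from_newick("((A:0,B:0):1,C:1);")
        with pytest.raises(DegenerateDataError):
            pic(t, pd.Series({"A": 1.0, "B": 2.0, "C": 3.0}))


class TestPicCorrelation:
    def test_exact_linear_relation_gives_unit_correlation(self, balanced_tree):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=8), index=sorted(balanced_tree.tip_labels))
        r, p = pic_correlation(balanced_tree, x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_positive_relation_recovered_under_noise(self):
        tree = _simulated_tribal_tree(seed=6, n_tribes=30)
        rng = np.random.default_rng(6)
        hits = 0
        for i in range(20):
            x = simulate_bm(tree, 1.0, 1, seed=100 + i).iloc[0]
            y = x + simulate_bm(tree, 0.25, 1, seed=500 + i).iloc[0]
            r, p = pic_correlation(tree, x, y)
            hits += r > 0
        assert hits >= 18


def _simulated_tribal_tree(seed: int, n_tribes: int) -> DatedTree:
    from phylodisp.simulate import SimConfig, simulate_tree
    from phylodisp.trees import prune_to_tribes

    tree, tax = simulate_tree(SimConfig(seed=seed, n_tribes=n_tribes))
    return prune_to_tribes(tree, tax.genus_to_tribe)


class TestPhylAnova:
    def test_star_tree_limit_recovers_standard_anova(self):
        n = 60
        nwk = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        t = DatedTree.from_newick(nwk)
        rng = np.random.default_rng(5)
        labels = t.tip_labels
        trait = pd.Series(rng.normal(size=n), index=labels)
        groups = pd.Series(["a", "b", "c"] * (n // 3), index=labels)
        res = phyl_anova(t, groups, trait, n_sim=2000, seed=9, posthoc=False)
        assert res.p_phyl == pytest.approx(res.p_standard, abs=0.05)

    def test_deep_clade_grouping_absorbed_by_null(self):
        # groups follow the two deepest clades; a pure BM trait then looks
        # "significant" to standard ANOVA but not against the BM null
        tree = _simulated_tribal_tree(seed=13, n_tribes=24)
        root_kids = tree.tree.seed_node.child_nodes()
        groups = {}
        for i, kid in enumerate(root_kids):
            for leaf in kid.leaf_iter():
                groups[leaf.taxon.label] = f"clade{i}"
        groups = pd.Series(groups)
        trait = simulate_bm(tree, 1.0, 1, seed=21).iloc[0]
        res = phyl_anova(tree, groups, trait, n_sim=500, seed=3, posthoc=False)
        assert res.p_phyl > res.p_standard

    def test_posthoc_bonferroni_bounds(self):
        tree = _simulated_tribal_tree(seed=10, n_tribes=21)
        labels = tree.tip_labels
        groups = pd.Series([["a", "b", "c"][i % 3] for i in range(len(labels))], index=labels)
        trait = simulate_bm(tree, 1.0, 1, seed=1).iloc[0] + (groups == "a") * 5
        res = phyl_anova(tree, groups, trait, n_sim=300, seed=2)
        p = res.posthoc_p.to_numpy()
        off = p[~np.isnan(p)]
        assert np.all((off >= 1 / 301) & (off <= 1.0))
        assert res.p_phyl >= 1 / 301

    def test_small_group_rejected(self, balanced_tree):
        labels = sorted(balanced_tree.tip_labels)
        groups = pd.Series(["a"] * 7 + ["b"], index=labels)
        trait = pd.Series(np.arange(8.0), index=labels)
        with pytest.raises(ValidationError, match="< 2 tips"):
            phyl_anova(balanced_tree, groups, trait, n_sim=10)


class TestLineageRankTests:
    def test_kw_statistic_matches_hand_midrank_computation(self):
        # 9 observations, one tie pair; rank sums 9, 14, 22 give
        # H = (12/90 * (81+196+484)/3 - 30) / (1 - 6/720) = 3.8543417...
        values = pd.Series(
            [1, 2, 5, 3, 3, 7, 8, 9, 4],
            index=[f"t{i}" for i in range(9)],
            dtype=float,
        )
        lin = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=values.index)
        res = lineage_rank_tests(values, lin)
        assert res.kw_statistic == pytest.approx(3.8543417366946784, rel=1e-9)
        assert res.pairwise_p is None  # not significant, no posthoc

    def test_strong_shift_detected_with_pairwise_tests(self):
        a = [0.1, 0.9, -0.5, 1.2, -1.1, 0.3, 0.7, -0.2]
        b = [0.2, 0.8, -0.4, 1.1, -1.0, 0.4, 0.6, -0.3]
        c = [10.1, 10.9, 9.5, 11.2, 8.9, 10.3, 10.7, 9.8]
        values = pd.Series(a + b + c, index=[f"t{i}" for i in range(24)])
        lin = pd.Series(["A"] * 8 + ["B"] * 8 + ["C"] * 8, index=values.index)
        res = lineage_rank_tests(values, lin)
        assert res.kw_p < 0.001
        assert res.pairwise_p.loc["A", "C"] < 0.01
        assert res.pairwise_p.loc["A", "B"] > 0.05

    def test_all_tied_values_rejected(self):
        values = pd.Series([1.0] * 6, index=[f"t{i}" for i in range(6)])
        lin = pd.Series(["A"] * 3 + ["B"] * 3, index=values.index)
        with pytest.raises(DegenerateDataError):
            lineage_rank_tests(values, lin)
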