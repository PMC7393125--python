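import numpy as np
import pandas as pd
import pytest

from phylodisp.ages import (
    TribeAges,
    calibrate_and_impute,
    extract_ages,
    genome_size_variation,
    summarize_ages,
    wgd_rate,
)
from phylodisp.errors import ValidationError
from phylodisp.simulate import SimConfig, simulate_tree
from phylodisp.trees import DatedTree


class TestExtractAges:
    def test_two_genus_tribe_read_off_topology(self):
        t = DatedTree.from_newick("((A:5,B:5):3,C:8);")
        ages = extract_ages(t, {"A": "X", "B": "X", "C": "Y"})
        row = ages.table.loc["X"]
        assert row["stem"] == pytest.approx(8.0)
        assert row["crown"] == pytest.approx(5.0)
        assert row["lag"] == pytest.approx(3.0)

    def test_single_genus_tribe_has_no_crown_age(self):
        t = DatedTree.from_newick("((A:5,B:5):3,C:8);")
        ages = extract_ages(t, {"A": "X", "B": "X", "C": "Y"})
        assert np.isnan(ages.table.loc["Y", "crown"])
        assert np.isnan(ages.table.loc["Y", "lag"])
        assert ages.table.loc["Y", "stem"] == pytest.approx(8.0)

    def test_matches_independent_node_traversal(self):
        # oracle: recompute stem/crown by walking node depths directly
        for seed in range(5):
            tree, tax = simulate_tree(SimConfig(seed=seed, n_tribes=12))
            ages = extract_ages(tree, tax.genus_to_tribe)
            depths = {}
            for nd in tree.tree.preorder_node_iter():
                d = 0.0 if nd.parent_node is None else depths[id(nd.parent_node)] + nd.edge.length
                depths[id(nd)] = d
            root_age = max(depths[id(l)] for l in tree.tree.leaf_node_iter())
            by_tribe = {}
            for leaf in tree.tree.leaf_node_iter():
                by_tribe.setdefault(tax.genus_to_tribe[leaf.taxon.label], []).append(leaf)
            for tribe, leaves in by_tribe.items():
                anc_sets = []
                for leaf in leaves:
                    anc = []
                    nd = leaf
                    while nd is not None:
                        anc.append(id(nd))
                        nd = nd.parent_node
                    anc_sets.append(anc)
                common = set(anc_sets[0]).intersection(*map(set, anc_sets[1:])) if len(anc_sets) > 1 else set(anc_sets[0][1:])
                mrca_id = max(common, key=lambda i: depths[i]) if len(leaves) > 1 else None
                if mrca_id is not None:
                    crown = root_age - depths[mrca_id]
                    assert ages.table.loc[tribe, "crown"] == pytest.approx(crown, rel=1e-9)
                assert ages.table.loc[tribe, "lag"] >= -1e-9 or np.isnan(
                    ages.table.loc[tribe, "lag"]
                )

    def test_merged_polytomy_group_shares_one_crown_age(self):
        t = DatedTree.from_newick("(((A:2,B:2):2,(C:3,D:3):1):4,E:8);")
        g2t = {"A": "T1", "B": "T1", "C": "T2", "D": "T2", "E": "T3"}
        ages = extract_ages(t, g2t, merge_groups={"T1+T2": ["T1", "T2"]})
        assert ages.table.loc["T1", "crown"] == pytest.approx(4.0)
        assert ages.table.loc["T2", "crown"] == pytest.approx(4.0)
        assert ages.table.loc["T1", "stem"] == pytest.approx(8.0)


class TestCalibration:
    def _ages(self):
        table = pd.DataFrame(
            {
                "stem": [10.0, 12.0, 9.0, 14.0, 11.0],
                "crown": [7.0, 9.0, 5.0, np.nan, np.nan],
                "crown_source": ["tree", "tree", "tree", None, None],
            },
            index=["t1", "t2", "t3", "t4", "t5"],
        )
        table["lag"] = table["stem"] - table["crown"]
        return TribeAges(table)

    def test_identity_calibration_passes_values_through(self):
        ages = self._ages()
        external = {"t1": 7.0, "t2": 9.0, "t3": 5.0, "t4": 8.0}
        model, filled = calibrate_and_impute(ages, external)
        assert model.spearman_rho == pytest.approx(1.0)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert filled.table.loc["t4", "crown"] == pytest.approx(8.0)
        assert filled.table.loc["t4", "crown_source"] == "imputed"
        assert np.isnan(filled.table.loc["t5", "crown"])  # no external value

    def test_scaled_external_ages_recovered(self):
        # external = tree/0.9 + noise; the fitted slope must invert the scaling
        rng = np.random.default_rng(0)
        slopes = []
        for rep in range(50):
            tree_crown = rng.uniform(3, 15, size=12)
            stem = tree_crown + rng.uniform(1, 5, size=12)
            ext = tree_crown / 0.9 + rng.normal(0, 0.2, size=12)
            table = pd.DataFrame(
                {"stem": stem, "crown": tree_crown, "crown_source": "tree"},
                index=[f"t{i}" for i in range(12)],
            )
            table["lag"] = table["stem"] - table["crown"]
            model, _ = calibrate_and_impute(
                TribeAges(table), {f"t{i}": ext[i] for i in range(12)}
            )
            slopes.append(model.slope)
        assert np.mean(slopes) == pytest.approx(0.9, abs=0.02)

    def test_imputation_never_overwrites_and_clips_to_stem(self):
        ages = self._ages()
        external = {"t1": 7.0, "t2": 9.0, "t3": 5.0, "t4": 50.0}
        with pytest.warns(UserWarning, match="clipped"):
            model, filled = calibrate_and_impute(ages, external)
        assert filled.table.loc["t4", "crown"] == pytest.approx(14.0)  # clipped to stem
        assert filled.table.loc["t1", "crown"] == 7.0
        assert filled.table.loc["t1", "crown_source"] == "tree"

    def test_too_few_pairs_rejected(self):
        ages = self._ages()
        with pytest.raises(ValidationError):
            calibrate_and_impute(ages, {"t1": 7.0, "t2": 9.0})


class TestWgdRate:
    @pytest.mark.parametrize(
        "mean_wgds,my,expected",
        [(1.45, 35.0, 0.41), (4.0, 440.0, 0.09), (0.0, 12.0, 0.0)],
    )
    def test_rate_per_10_my(self, mean_wgds, my, expected):
        assert round(wgd_rate(mean_wgds, my), 2) == expected

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            wgd_rate(1.0, 0.0)


class TestGenomeSizeVariation:
    def test_cv_with_minimum_three_estimates(self):
        cv = genome_size_variation(
            {"a": [1.0, 1.0, 1.0], "b": [2.0, 4.0], "c": [1.0, 2.0, 3.0]}
        )
        assert cv["a"] == 0.0
        assert np.isnan(cv["b"])  # below the 3-taxon threshold
        assert cv["c"] == pytest.approx(0.5)  # sample SD 1 / mean 2

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValidationError):
            genome_size_variation({"a": [1.0, -2.0, 3.0]})


class TestSummaries:
    def test_mean_and_sample_sd(self):
        table = pd.DataFrame(
            {"stem": [10.0, 20.0], "crown": [4.0, 6.0], "crown_source": "tree"},
            index=["a", "b"],
        )
        table["lag"] = table["stem"] - table["crown"]
        s = summarize_ages(TribeAges(table))
        assert s.loc["stem", "mean"] == pytest.approx(15.0)
        assert s.loc["stem", "sd"] == pytest.approx(7.0710678, rel=1e-6)

    def test_lag_summary_excludes_single_genus_tribes(self):
        table = pd.DataFrame(
            {
                "stem": [10.0, 20.0, 5.0],
                "crown": [4.0, 6.0, np.nan],
                "crown_source": ["tree", "tree", None],
            },
            index=["a", "b", "c"],
        )
        table["lag"] = table["stem"] - table["crown"]
        s = summarize_ages(TribeAges(table))
        assert s.loc["lag", "n"] == 2
        assert s.loc["stem", "n"] == 3
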