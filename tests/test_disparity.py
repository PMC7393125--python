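import numpy as np
import pandas as pd
import pytest

from phylodisp.core_data import Character, MorphoMatrix, TaxonomyTable, aggregate_to_tribes
from phylodisp.disparity import (
    character_disparity,
    genus_disparity,
    lineage_state_frequencies,
    tribal_disparity_direct,
    tribal_disparity_from_genera,
)
from phylodisp.errors import ValidationError
from tests.conftest import random_morphomatrix, random_taxonomy

BINARY = Character("X1", "A", "binary", ("X1-1", "X1-2"))
FIVE = Character("X2", "A", "five-state", tuple(f"X2-{i}" for i in range(1, 6)))


class TestCharacterDisparity:
    @pytest.mark.parametrize(
        "observed,char,expected",
        [
            ({"X1-1"}, BINARY, 0.5),  # lower bound 1/k
            ({"X1-1", "X1-2"}, BINARY, 1.0),  # all states realized
            ({"X2-1", "X2-3", "X2-5"}, FIVE, 0.6),  # 3 of 5
        ],
    )
    def test_fraction_of_states(self, observed, char, expected):
        assert character_disparity(observed, char) == pytest.approx(expected)

    def test_empty_set_is_missing_not_zero(self):
        with pytest.raises(ValidationError):
            character_disparity(set(), BINARY)

    def test_foreign_state_rejected(self):
        with pytest.raises(ValidationError):
            character_disparity({"X2-1"}, BINARY)


class TestTribalDisparity:
    def test_direct_matches_per_cell_recomputation(self, toy_scheme):
        rng = np.random.default_rng(5)
        m = random_morphomatrix(toy_scheme, 16, rng)
        tax = random_taxonomy(m.genera, 4, rng)
        tsm = aggregate_to_tribes(m, tax)
        table = tribal_disparity_direct(tsm)
        for tribe in tsm.tribes:
            for char in toy_scheme:
                states = tsm.states_of(tribe, char.id)
                got = table.values.loc[tribe, char.id]
                if tsm.scored.loc[tribe, char.id]:
                    assert got == pytest.approx(character_disparity(states, char))
                else:
                    assert np.isnan(got)

    def test_between_genus_polymorphism_splits_the_two_routes(self, toy_scheme, toy_taxonomy):
        # two genera carrying different single states of a binary character:
        # the union realizes both (direct = 1), each genus realizes one (mean = 0.5)
        cells = {("Arabis", "B03"): {"B03-1"}, ("Draba", "B03"): {"B03-2"}}
        m = MorphoMatrix(toy_scheme, ["Arabis", "Draba"], cells)
        tsm = aggregate_to_tribes(m, toy_taxonomy)
        direct = tribal_disparity_direct(tsm).values.loc["Arabideae", "B03"]
        fromg = tribal_disparity_from_genera(m, toy_taxonomy).values.loc["Arabideae", "B03"]
        assert direct == 1.0 and fromg == 0.5

    def test_single_genus_tribe_routes_agree(self, toy_matrix, toy_taxonomy):
        tsm = aggregate_to_tribes(toy_matrix, toy_taxonomy)
        direct = tribal_disparity_direct(tsm).values.loc["Lepidieae"]
        fromg = tribal_disparity_from_genera(toy_matrix, toy_taxonomy).values.loc["Lepidieae"]
        pd.testing.assert_series_equal(direct, fromg, check_names=False)

    def test_direct_dominates_from_genera_on_random_matrices(self, toy_scheme):
        rng = np.random.default_rng(123)
        for _ in range(25):
            m = random_morphomatrix(toy_scheme, 15, rng)
            tax = random_taxonomy(m.genera, 4, rng)
            tsm = aggregate_to_tribes(m, tax)
            d = tribal_disparity_direct(tsm).values
            f = tribal_disparity_from_genera(m, tax).values.reindex(d.index)
            diff = (d - f).to_numpy()
            assert np.all((diff >= -1e-12) | np.isnan(diff))

    def test_bounds_and_mean_skips_missing(self, toy_matrix, toy_taxonomy):
        gd = genus_disparity(toy_matrix)
        for char in toy_matrix.scheme:
            col = gd.values[char.id].dropna()
            assert ((col >= 1 / char.k - 1e-12) & (col <= 1 + 1e-12)).all()
        # Draba scored for B03 (0.5) and B04 (1/3) only; D10 must not drag the mean
        assert gd.mean_disparity["Draba"] == pytest.approx((0.5 + 1 / 3) / 2)

    def test_genus_order_permutation_leaves_outputs_unchanged(self, toy_scheme):
        rng = np.random.default_rng(9)
        m = random_morphomatrix(toy_scheme, 10, rng)
        tax = random_taxonomy(m.genera, 3, rng)
        shuffled = MorphoMatrix(toy_scheme, m.genera[::-1], m.cells)
        a = tribal_disparity_from_genera(m, tax).values
        b = tribal_disparity_from_genera(shuffled, tax).values
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestLineageFrequencies:
    def _lineage_world(self, toy_scheme):
        """Seven lineage-III tribes, four of which carry B03-2; one lineage-I tribe."""
        genera, cells, g2t, lineages = [], {}, {}, {}
        for i in range(7):
            t = f"iii{i}"
            g = f"g{i}"
            genera.append(g)
            g2t[g] = t
            lineages[t] = "III"
            cells[(g, "B03")] = {"B03-1", "B03-2"} if i < 4 else {"B03-1"}
        genera.append("gx")
        g2t["gx"] = "one"
        lineages["one"] = "I"
        cells[("gx", "B03")] = {"B03-1"}
        m = MorphoMatrix(toy_scheme, genera, cells)
        tax = TaxonomyTable(genus_to_tribe=g2t, lineage_schemes={"lineage": lineages})
        return m, tax

    def test_state_restricted_to_four_of_seven_tribes(self, toy_scheme):
        m, tax = self._lineage_world(toy_scheme)
        freqs = lineage_state_frequencies(aggregate_to_tribes(m, tax), tax)
        assert freqs.frequencies.loc["III", "B03-2"] == pytest.approx(4 / 7)
        assert freqs.frequencies.loc["I", "B03-2"] == 0.0
        row = freqs.pairwise.query("state == 'B03-2'")
        assert row["difference"].iloc[0] == pytest.approx(4 / 7)

    def test_shared_state_has_zero_difference(self, toy_scheme):
        m, tax = self._lineage_world(toy_scheme)
        freqs = lineage_state_frequencies(aggregate_to_tribes(m, tax), tax)
        assert freqs.pairwise.query("state == 'B03-1'")["difference"].iloc[0] == 0.0

    def test_matches_brute_force_counting(self, toy_scheme):
        rng = np.random.default_rng(31)
        m = random_morphomatrix(toy_scheme, 24, rng, missing=0.2)
        tax = random_taxonomy(m.genera, 8, rng, n_lineages=3)
        tsm = aggregate_to_tribes(m, tax)
        freqs = lineage_state_frequencies(tsm, tax)
        for lineage in freqs.frequencies.index:
            tribes = [t for t in tax.tribes_of_lineage(lineage) if t in tsm.presence.index]
            for state in toy_scheme.state_ids:
                char = toy_scheme.owner(state)
                scored = [t for t in tribes if tsm.scored.loc[t, char]]
                got = freqs.frequencies.loc[lineage, state]
                if not scored:
                    assert np.isnan(got)
                else:
                    expect = sum(tsm.presence.loc[t, state] for t in scored) / len(scored)
                    assert got == pytest.approx(expect)

    def test_frequencies_and_differences_bounded(self, toy_scheme):
        rng = np.random.default_rng(77)
        m = random_morphomatrix(toy_scheme, 30, rng)
        tax = random_taxonomy(m.genera, 6, rng)
        freqs = lineage_state_frequencies(aggregate_to_tribes(m, tax), tax)
        vals = freqs.frequencies.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
        assert freqs.pairwise["difference"].between(0, 1).all()
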