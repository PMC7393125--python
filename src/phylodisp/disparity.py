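"""The disparity statistic and lineage-level character-state frequencies.

Disparity of a character within a taxon is the fraction of that character's
states realized at the taxon's level: with ``k`` possible states and ``r``
observed, disparity = ``r / k``, ranging from ``1/k`` (a single state
realized) to 1 (all states realized).  Tribal disparity comes in two
flavours:

* *direct* — computed from the tribal presence/absence matrix (union of the
  member genera's states);
* *from genera* — the mean of the member genera's disparity values.

Because a union can only grow, direct disparity is never lower than
disparity from genera; this dominance is a structural property and is
enforced by the test suite.

Mean disparity per taxon is the unweighted mean over characters with data;
characters missing in a taxon are dropped from that taxon's mean, not
counted as zero.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from phylodisp.core_data import (
    Character,
    CharacterScheme,
    MorphoMatrix,
    TaxonomyTable,
    TribalStateMatrix,
)
from phylodisp.errors import DegenerateDataError, ValidationError


class DisparityTable:
    """Per-taxon, per-character disparity values plus row means.

    ``values`` is a DataFrame (taxa x character ids) with NaN where a taxon
    has no data for a character; ``method`` records the aggregation route.
    """

    def __init__(self, values: pd.DataFrame, scheme: CharacterScheme, method: str):
        self.values = values
        self.scheme = scheme
        self.method = method

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def mean_disparity(self) -> pd.Series:
        """Unweighted mean over characters with data (NaN-aware)."""
        return self.values.mean(axis=1, skipna=True)

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per (taxon, character) with data."""
        long = (
            self.values.rename_axis(index="taxon", columns="character")
            .stack()
            .rename("disparity")
            .reset_index()
        )
        long["method"] = self.method
        return long

    def to_heatmap_frame(self, taxon_order: Iterable[str] | None = None) -> pd.DataFrame:
        """Wide matrix with taxa in a supplied (e.g. tree) order and
        characters sorted by mean disparity, descending."""
        df = self.values
        if taxon_order is not None:
            df = df.loc[[t for t in taxon_order if t in df.index]]
        char_order = df.mean(axis=0, skipna=True).sort_values(ascending=False).index
        return df[char_order]


def character_disparity(observed_states: Iterable[str], character: Character) -> float:
    """Fraction of a character's states realized: ``|observed| / k``.

    An empty observation set is a *missing* value and raises; callers encode
    missingness as NaN, never as zero disparity.
    """
    observed = frozenset(observed_states)
    if not observed:
        raise ValidationError(
            f"character {character.id!r}: empty state set is missing data, not zero disparity"
        )
    extra = observed - set(character.states)
    if extra:
        raise ValidationError(
            f"character {character.id!r}: states {sorted(extra)} not in the character"
        )
    return len(observed) / character.k


def genus_disparity(m: MorphoMatrix) -> DisparityTable:
    """Genus-level disparity table (one row per genus)."""
    data = {}
    for char in m.scheme:
        col = []
        for g in m.genera:
            states = m.states_of(g, char.id)
            col.append(character_disparity(states, char) if states else np.nan)
        data[char.id] = col
    values = pd.DataFrame(data, index=pd.Index(m.genera, name="genus"))
    return DisparityTable(values, m.scheme, method="genus")


def tribal_disparity_direct(tsm: TribalStateMatrix) -> DisparityTable:
    """Tribal disparity computed directly from the tribal presence matrix."""
    scheme = tsm.scheme
    data = {}
    for char in scheme:
        cols = list(char.states)
        counts = tsm.presence[cols].sum(axis=1)
        vals = counts / char.k
        vals[~tsm.scored[char.id]] = np.nan
        data[char.id] = vals
    values = pd.DataFrame(data)
    values.index.name = "tribe"
    return DisparityTable(values, scheme, method="direct")


def tribal_disparity_from_genera(m: MorphoMatrix, tax: TaxonomyTable) -> DisparityTable:
    """Tribal disparity as the mean of member-genus disparity values.

    Only genera scored for a character enter that character's mean; a tribe
    with no scored genus for a character gets NaN.
    """
    gd = genus_disparity(m)
    rows = {}
    genus_set = set(m.genera)
    for tribe in tax.tribes:
        members = [g for g in tax.genera_of(tribe) if g in genus_set]
        if not members:
            continue
        rows[tribe] = gd.values.loc[members].mean(axis=0, skipna=True)
    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "tribe"
    values = values[m.scheme.character_ids]
    return DisparityTable(values, m.scheme, method="from_genera")


def mean_disparity(table: DisparityTable) -> pd.Series:
    """Convenience alias for the per-taxon unweighted mean."""
    return table.mean_disparity


class LineageFrequencyTable:
    """Per-lineage character-state frequencies and pairwise differences.

    ``frequencies`` is a DataFrame (lineages x state ids); the frequency of
    a state in a lineage is the fraction of that lineage's tribes *scored
    for the character* in which the state is present.  ``pairwise`` is a
    long DataFrame of absolute frequency differences per state for every
    unordered lineage pair.
    """

    def __init__(self, frequencies: pd.DataFrame, pairwise: pd.DataFrame):
        self.frequencies = frequencies
        self.pairwise = pairwise

    def max_pairwise_difference(self) -> float:
        return float(self.pairwise["difference"].max())


def lineage_state_frequencies(
    tsm: TribalStateMatrix, tax: TaxonomyTable, scheme: str = "lineage"
) -> LineageFrequencyTable:
    """Character-state frequencies per lineage from the tribal matrix.

    The denominator for a state is the number of the lineage's tribes with
    the owning character scored, so missing data deflate neither presence
    nor absence.
    """
    if scheme not in tax.lineage_schemes:
        raise ValidationError(f"unknown lineage scheme {scheme!r}")
    lineages = sorted(set(tax.lineage_schemes[scheme].values()))
    freq = pd.DataFrame(
        np.nan, index=pd.Index(lineages, name="lineage"), columns=tsm.presence.columns
    )
    for lineage in lineages:
        tribes = [t for t in tax.tribes_of_lineage(lineage, scheme) if t in tsm.presence.index]
        if not tribes:
            raise DegenerateDataError(f"lineage {lineage!r} has no tribes in the matrix")
        for char in tsm.scheme:
            scored = [t for t in tribes if tsm.scored.loc[t, char.id]]
            if not scored:
                continue
            sub = tsm.presence.loc[scored, list(char.states)]
            freq.loc[lineage, list(char.states)] = sub.mean(axis=0).values
    records = []
    for a, b in combinations(lineages, 2):
        diff = (freq.loc[a] - freq.loc[b]).abs()
        for state, d in diff.items():
            if not np.isnan(d):
                records.append((a, b, state, float(d)))
    pairwise = pd.DataFrame(records, columns=["lineage_a", "lineage_b", "state", "difference"])
    return LineageFrequencyTable(freq, pairwise)
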