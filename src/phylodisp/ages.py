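"""Stem/crown ages, lag-phase, cross-study calibration and WGD arithmetic.

For a tribe on a dated tree, the *stem age* is the age of the split between
the tribe and its sister lineage (the parent node of the tribe's subtending
branch), the *crown age* is the age of the tribe's most recent common
ancestor (undefined for single-genus tribes), and the *lag-phase* is
stem - crown: the window of zero net diversification for the surviving
lineage between its origin and its first split.

Crown ages missing from the focal tree can be imputed from an external
study via a calibration regression (external age as predictor, tree-scale
age as response), after checking agreement with Spearman's rank
correlation.  Imputed values never overwrite tree-derived ones and are
clipped to the stem age when the regression overshoots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from phylodisp.errors import ValidationError
from phylodisp.trees import DatedTree


@dataclass
class TribeAges:
    """Per-tribe stem/crown ages (my), their source, and the lag-phase."""

    table: pd.DataFrame  # index tribe; columns stem, crown, crown_source, lag

    def __post_init__(self) -> None:
        t = self.table
        both = t.dropna(subset=["stem", "crown"])
        bad = both[both["crown"] > both["stem"] + 1e-9]
        if not bad.empty:
            raise ValidationError(f"crown age exceeds stem age for: {list(bad.index)}")

    @property
    def tribes(self) -> list[str]:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        self.table.rename_axis("tribe").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TribeAges":
        return cls(pd.read_csv(path, index_col="tribe"))


def extract_ages(
    tree: DatedTree,
    genus_to_tribe: dict[str, str | None],
    merge_groups: dict[str, list[str]] | None = None,
) -> TribeAges:
    """Extract stem and crown ages for every tribe with tips on the tree.

    Tribes must be monophyletic.  ``merge_groups`` maps a group name to a
    list of tribes that are treated as a single age group (used when the
    tree cannot resolve closely related tribes beyond a polytomy): the
    group's tips are pooled and each member tribe receives the pooled stem
    and crown age.
    """
    tip_set = set(tree.tip_labels)
    tribe_tips: dict[str, list[str]] = {}
    for genus, tribe in genus_to_tribe.items():
        if tribe is not None and genus in tip_set:
            tribe_tips.setdefault(tribe, []).append(genus)
    merged_members: dict[str, str] = {}
    if merge_groups:
        for gname, members in merge_groups.items():
            pooled: list[str] = []
            for m in members:
                pooled.extend(tribe_tips.pop(m, []))
                merged_members[m] = gname
            if pooled:
                tribe_tips[gname] = pooled
    rows = {}
    for tribe, tips in sorted(tribe_tips.items()):
        if len(tips) > 1 and not tree.is_monophyletic(tips):
            raise ValidationError(f"tribe {tribe!r} is not monophyletic on the tree")
        node = tree.mrca(tips)
        if len(tips) == 1:
            crown = np.nan
            stem_node = node.parent_node
        else:
            crown = tree.age_of(node)
            stem_node = node.parent_node
        stem = tree.root_age if stem_node is None else tree.age_of(stem_node)
        rows[tribe] = (stem, crown, "tree" if not np.isnan(crown) else None)
    # expand merged groups back to their member tribes
    for member, gname in merged_members.items():
        if gname in rows:
            rows[member] = rows[gname]
    for gname in set(merged_members.values()):
        rows.pop(gname, None)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["stem", "crown", "crown_source"])
    table.index.name = "tribe"
    table = table.sort_index()
    table["lag"] = table["stem"] - table["crown"]
    return TribeAges(table)


@dataclass
class CalibrationModel:
    """OLS calibration of tree-scale crown ages against an external study."""

    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float
    n_pairs: int
    pairs: pd.DataFrame = field(repr=False, default=None)

    def predict(self, external_age: float) -> float:
        return self.intercept + self.slope * external_age


def calibrate_and_impute(
    ages: TribeAges, external: dict[str, float] | pd.Series
) -> tuple[CalibrationModel, TribeAges]:
    """Fit the calibration line and fill missing crown ages.

    External (e.g. ITS-based) crown ages are the predictor, the focal
    tree's ages the response; tribes with both estimates define the fit
    (>= 3 required).  Tribes lacking a tree-derived crown age but present
    in ``external`` receive the regression prediction, flagged
    ``"imputed"``; predictions above the stem age are clipped to it with a
    warning.  Tree-derived crown ages are never overwritten.
    """
    external = pd.Series(external, dtype=float)
    t = ages.table.copy()
    have_both = t.index[t["crown"].notna() & t.index.isin(external.index)]
    if len(have_both) < 3:
        raise ValidationError(f"need >= 3 tribes with both estimates, got {len(have_both)}")
    x = external[have_both].to_numpy()
    y = t.loc[have_both, "crown"].to_numpy(dtype=float)
    rho, rho_p = stats.spearmanr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    model = CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n_pairs=len(have_both),
        pairs=pd.DataFrame({"external": x, "tree": y}, index=have_both),
    )
    clipped = []
    for tribe in t.index:
        if pd.isna(t.loc[tribe, "crown"]) and tribe in external.index:
            pred = model.predict(external[tribe])
            stem = t.loc[tribe, "stem"]
            if pred > stem:
                clipped.append(tribe)
                pred = stem
            t.loc[tribe, "crown"] = pred
            t.loc[tribe, "crown_source"] = "imputed"
    if clipped:
        warnings.warn(f"imputed crown ages clipped to stem age for: {clipped}")
    t["lag"] = t["stem"] - t["crown"]
    return model, TribeAges(t)


def wgd_rate(mean_wgds_per_genus: float, elapsed_my: float) -> float:
    """Whole-genome-duplication rate per 10 my.

    ``mean_wgds_per_genus / elapsed_my * 10``; e.g. a mean of 1.45 WGDs per
    genus accumulated over 35 my gives 0.41 WGD / 10 my.
    """
    if elapsed_my <= 0:
        raise ValidationError("elapsed time must be positive")
    if mean_wgds_per_genus < 0:
        raise ValidationError("mean WGD count cannot be negative")
    return mean_wgds_per_genus / elapsed_my * 10.0


def genome_size_variation(sizes_by_tribe: dict[str, list[float]]) -> pd.Series:
    """Coefficient of variation of genome size per tribe.

    SD (sample, n-1) divided by the mean, restricted to tribes with at
    least three estimates; tribes below the threshold get NaN.
    """
    out = {}
    for tribe, sizes in sizes_by_tribe.items():
        arr = np.asarray(sizes, dtype=float)
        if np.any(arr <= 0):
            raise ValidationError(f"tribe {tribe!r}: non-positive genome size")
        out[tribe] = float(arr.std(ddof=1) / arr.mean()) if arr.size >= 3 else np.nan
    return pd.Series(out, name="genome_size_cv")


def summarize_ages(ages: TribeAges) -> pd.DataFrame:
    """Mean and sample SD of stem, crown and lag over tribes with data."""
    rows = {}
    for col in ("stem", "crown", "lag"):
        vals = ages.table[col].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            rows[col] = (np.nan, np.nan, vals.size)
        else:
            rows[col] = (float(vals.mean()), float(vals.std(ddof=1)), vals.size)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["mean", "sd", "n"])
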