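"""Comparative statistics on dated trees.

Implements the statistics used downstream of the disparity tables:

* **Moran's I** phylogenetic signal with a tip-permutation null.  The
  default proximity is the inverse patristic distance, zero diagonal,
  row-standardized; other weight matrices can be supplied.
* **Brownian-motion simulation** along the tree (the null generator for the
  phylogenetic ANOVA), vectorized over replicates.
* **Phylogenetic ANOVA**: the observed one-way F statistic referred to a
  null distribution of F values computed from Brownian simulations on the
  tree, with simulation-based post-hoc pairwise t tests and Bonferroni
  correction.
* **Phylogenetically independent contrasts** (Felsenstein's algorithm) and
  the through-origin contrast correlation.
* **Rank-based lineage tests**: Kruskal-Wallis followed by pairwise
  Wilcoxon rank-sum tests with Bonferroni correction, for data that are
  per se highly phylogenetically structured.

All stochastic operations take an explicit integer seed and record it in
their result objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from phylodisp.errors import DegenerateDataError, ValidationError
from phylodisp.trees import DatedTree

# ---------------------------------------------------------------------------
# tree -> arrays


def _tree_arrays(tree: DatedTree):
    """Postorder arrays: (parent index, edge length, tip flag, labels).

    Index 0..n_nodes-1 follows a preorder numbering so every parent index is
    smaller than its child's; the root has parent -1 and length 0.
    """
    nodes = list(tree.tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    length = np.zeros(len(nodes))
    tip_idx = []
    labels = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            length[i] = nd.edge.length
        if nd.is_leaf():
            tip_idx.append(i)
            labels.append(nd.taxon.label)
    return parent, length, np.array(tip_idx), labels


# ---------------------------------------------------------------------------
# Moran's I


@dataclass
class SignalResult:
    """Moran's I for one variable on one tree."""

    name: str
    morans_i: float
    expected_null: float
    p_value: float
    n_perm: int
    seed: int


def inverse_patristic_weights(tree: DatedTree, row_standardize: bool = True) -> pd.DataFrame:
    """Proximity matrix w_ij = 1/patristic distance, zero diagonal."""
    d = tree.patristic_matrix()
    w = d.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        w = np.where(w > 0, 1.0 / w, 0.0)
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rowsum = w.sum(axis=1, keepdims=True)
        if np.any(rowsum == 0):
            raise ValidationError("proximity matrix has an all-zero row")
        w = w / rowsum
    return pd.DataFrame(w, index=d.index, columns=d.columns)


def _morans_i_stat(z: np.ndarray, w: np.ndarray) -> float:
    n = z.size
    big_w = w.sum()
    return float(n / big_w * (z @ w @ z) / (z @ z))


def morans_i(
    values: pd.Series,
    tree: DatedTree,
    n_perm: int = 999,
    seed: int = 0,
    weights: pd.DataFrame | None = None,
    name: str = "",
) -> SignalResult:
    """Moran's I with a two-sided tip-permutation test.

    I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Under exchangeability E[I] = -1/(n-1).  The permutation p value doubles
    the smaller one-tailed add-one estimate, capped at 1.
    """
    if weights is None:
        weights = inverse_patristic_weights(tree)
    labels = list(weights.index)
    x = values.reindex(labels).to_numpy(dtype=float)
    if np.any(np.isnan(x)):
        missing = [l for l, v in zip(labels, x) if np.isnan(v)]
        raise ValidationError(f"missing trait values for tips: {missing[:5]}")
    n = x.size
    if n < 4:
        raise ValidationError("Moran's I needs at least 4 tips")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise DegenerateDataError("constant trait: Moran's I is undefined")
    w = weights.to_numpy(dtype=float)
    i_obs = _morans_i_stat(z, w)
    rng = np.random.default_rng(seed)
    greater = lesser = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        i_p = _morans_i_stat(zp, w)
        if i_p >= i_obs:
            greater += 1
        if i_p <= i_obs:
            lesser += 1
    p_up = (1 + greater) / (n_perm + 1)
    p_dn = (1 + lesser) / (n_perm + 1)
    p = min(1.0, 2 * min(p_up, p_dn))
    return SignalResult(
        name=name,
        morans_i=i_obs,
        expected_null=-1.0 / (n - 1),
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Brownian motion


def simulate_bm(
    tree: DatedTree, rate: float, n_sim: int, seed: int = 0, root_value: float = 0.0
) -> pd.DataFrame:
    """Simulate Brownian traits: rows = replicates, columns = tip labels.

    Each branch contributes an independent normal increment with variance
    ``rate * branch_length``; a tip value is the root-to-tip sum, so two
    tips covary by ``rate *`` their shared path length.
    """
    if rate <= 0:
        raise ValidationError("BM rate must be > 0")
    parent, length, tip_idx, labels = _tree_arrays(tree)
    rng = np.random.default_rng(seed)
    incr = rng.standard_normal((n_sim, parent.size)) * np.sqrt(rate * length)
    vals = np.empty_like(incr)
    for i in range(parent.size):  # preorder: parent before child
        if parent[i] < 0:
            vals[:, i] = root_value
        else:
            vals[:, i] = vals[:, parent[i]] + incr[:, i]
    return pd.DataFrame(vals[:, tip_idx], columns=labels)


# ---------------------------------------------------------------------------
# contrasts


def pic(tree: DatedTree, trait: pd.Series) -> np.ndarray:
    """Felsenstein's phylogenetically independent contrasts.

    Polytomies are first resolved deterministically to zero-length
    branches.  Returns the n-1 standardized contrasts in the (fixed)
    postorder of the internal nodes.
    """
    bif = tree.bifurcating()
    x = {l: float(trait[l]) for l in bif.tip_labels}
    contrasts: list[float] = []
    node_val: dict[int, float] = {}
    node_bl: dict[int, float] = {}
    for nd in bif.tree.postorder_node_iter():
        if nd.is_leaf():
            node_val[id(nd)] = x[nd.taxon.label]
            node_bl[id(nd)] = nd.edge.length or 0.0
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:  # root with >2 children after resolution cannot occur
            raise ValidationError("pic requires a bifurcating tree")
        a, b = kids
        ba, bb = node_bl[id(a)], node_bl[id(b)]
        denom = ba + bb
        if denom <= 0:
            raise DegenerateDataError("zero contrast denominator (sister branches of length 0)")
        contrasts.append((node_val[id(a)] - node_val[id(b)]) / np.sqrt(denom))
        node_val[id(nd)] = (node_val[id(a)] * bb + node_val[id(b)] * ba) / denom
        node_bl[id(nd)] = (nd.edge.length or 0.0) + ba * bb / denom
    return np.asarray(contrasts)


def pic_correlation(tree: DatedTree, x: pd.Series, y: pd.Series) -> tuple[float, float]:
    """Correlation of two traits through the origin of their contrasts.

    r = sum(cx*cy) / sqrt(sum cx^2 * sum cy^2); the two-sided p value uses a
    t reference with n-2 degrees of freedom (one df spent on the root
    state, as in the standard contrasts regression through the origin).
    """
    cx = pic(tree, x)
    cy = pic(tree, y)
    sxx = float(cx @ cx)
    syy = float(cy @ cy)
    if sxx == 0 or syy == 0:
        raise DegenerateDataError("constant contrasts: correlation undefined")
    r = float(cx @ cy) / np.sqrt(sxx * syy)
    df = cx.size - 1
    if df < 1:
        raise DegenerateDataError("too few contrasts for a p value")
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def bm_rate_from_contrasts(tree: DatedTree, trait: pd.Series) -> float:
    """Brownian rate estimate: the mean squared standardized contrast."""
    c = pic(tree, trait)
    return float(np.mean(c**2))


# ---------------------------------------------------------------------------
# phylogenetic ANOVA


@dataclass
class PhylAnovaResult:
    """Phylogenetic ANOVA: observed F against a Brownian null on the tree."""

    f_obs: float
    p_phyl: float
    p_standard: float
    n_sim: int
    seed: int
    groups: list[str] = field(default_factory=list)
    posthoc_t: pd.DataFrame | None = None
    posthoc_p: pd.DataFrame | None = None


def _anova_f(x: np.ndarray, gidx: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """One-way ANOVA F, vectorized over rows of x (replicates x tips)."""
    n = x.shape[1]
    g = counts.size
    grand = x.mean(axis=1, keepdims=True)
    ssb = np.zeros(x.shape[0])
    means = np.empty((x.shape[0], g))
    for j in range(g):
        mj = x[:, gidx == j].mean(axis=1)
        means[:, j] = mj
        ssb += counts[j] * (mj - grand[:, 0]) ** 2
    sst = ((x - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    return (ssb / (g - 1)) / (ssw / (n - g)), means, ssw / (n - g)


def phyl_anova(
    tree: DatedTree,
    groups: pd.Series,
    trait: pd.Series,
    n_sim: int = 1000,
    seed: int = 0,
    posthoc: bool = True,
) -> PhylAnovaResult:
    """Simulation-based phylogenetic ANOVA.

    The observed one-way F is compared with F values obtained from ``n_sim``
    Brownian-motion simulations on the tree (rate = mean squared
    standardized contrast of the trait), giving
    ``p = (1 + #{F_sim >= F_obs}) / (n_sim + 1)``.  Post-hoc pairwise t
    statistics (pooled MSE) get simulation-based p values with Bonferroni
    correction over the number of pairs performed.
    """
    labels = tree.tip_labels
    x = trait.reindex(labels).to_numpy(dtype=float)
    if np.any(np.isnan(x)):
        raise ValidationError("trait missing for some tips")
    glab = groups.reindex(labels)
    if glab.isna().any():
        raise ValidationError("group missing for some tips")
    names = sorted(glab.unique())
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    gidx = np.array([names.index(g) for g in glab])
    counts = np.bincount(gidx, minlength=len(names)).astype(float)
    if counts.min() < 2:
        small = [names[i] for i in range(len(names)) if counts[i] < 2]
        raise ValidationError(f"groups with < 2 tips: {small}")
    n, g = x.size, len(names)
    f_obs_arr, means_obs, mse_obs = _anova_f(x[None, :], gidx, counts)
    f_obs = float(f_obs_arr[0])
    p_standard = float(stats.f.sf(f_obs, g - 1, n - g))

    rate = bm_rate_from_contrasts(tree, pd.Series(x, index=labels))
    sims = simulate_bm(tree, rate=rate, n_sim=n_sim, seed=seed)
    xs = sims[labels].to_numpy()
    f_sim, means_sim, mse_sim = _anova_f(xs, gidx, counts)
    p_phyl = float((1 + np.sum(f_sim >= f_obs)) / (n_sim + 1))

    result = PhylAnovaResult(
        f_obs=f_obs,
        p_phyl=p_phyl,
        p_standard=p_standard,
        n_sim=n_sim,
        seed=seed,
        groups=list(names),
    )
    if posthoc:
        pairs = list(combinations(range(g), 2))
        n_pairs = len(pairs)
        t_obs = pd.DataFrame(np.nan, index=names, columns=names)
        p_adj = pd.DataFrame(np.nan, index=names, columns=names)
        for i, j in pairs:
            se_fac = np.sqrt(1 / counts[i] + 1 / counts[j])
            tij = (means_obs[0, i] - means_obs[0, j]) / (np.sqrt(mse_obs[0]) * se_fac)
            t_sim = (means_sim[:, i] - means_sim[:, j]) / (np.sqrt(mse_sim) * se_fac)
            p_raw = (1 + np.sum(np.abs(t_sim) >= abs(tij))) / (n_sim + 1)
            t_obs.iloc[i, j] = t_obs.iloc[j, i] = tij
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = min(1.0, p_raw * n_pairs)
        result.posthoc_t = t_obs
        result.posthoc_p = p_adj
    return result


# ---------------------------------------------------------------------------
# rank-based lineage tests


@dataclass
class RankTestResult:
    """Kruskal-Wallis across groups plus optional pairwise Wilcoxon tests."""

    kw_statistic: float
    kw_p: float
    groups: list[str]
    pairwise_p: pd.DataFrame | None


def lineage_rank_tests(
    values: pd.Series, lineages: pd.Series, alpha: float = 0.05
) -> RankTestResult:
    """Kruskal-Wallis rank-sum test over lineages, with pairwise Wilcoxon
    rank-sum tests (Bonferroni-corrected) when the global test is
    significant at ``alpha``.  Ties are handled by midranks."""
    df = pd.DataFrame({"value": values, "lineage": lineages}).dropna()
    names = sorted(df["lineage"].unique())
    samples = [df.loc[df["lineage"] == g, "value"].to_numpy() for g in names]
    if len(names) < 2 or min(len(s) for s in samples) < 2:
        raise ValidationError("need >= 2 lineages with >= 2 tribes each")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values tied: rank tests undefined")
    kw_stat, kw_p = stats.kruskal(*samples)
    pairwise = None
    if kw_p < alpha:
        pairs = list(combinations(range(len(names)), 2))
        pairwise = pd.DataFrame(np.nan, index=names, columns=names)
        for i, j in pairs:
            _, p = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            pairwise.iloc[i, j] = pairwise.iloc[j, i] = min(1.0, p * len(pairs))
    return RankTestResult(
        kw_statistic=float(kw_stat), kw_p=float(kw_p), groups=names, pairwise_p=pairwise
    )
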