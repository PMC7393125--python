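"""Discriminant analysis of principal components (DAPC) on disparity data.

DAPC reduces the tribes x characters disparity matrix by PCA, then runs a
linear discriminant analysis on the retained principal-component scores
with lineage membership as the grouping prior, maximizing between-group
relative to within-group variation.  Data are centered but, by default,
not scaled (disparity values already live on a common [1/k, 1] scale);
scaling is available as an option.

Per-character contributions are the discriminant loadings mapped back
through the PCA rotation: for axis *a* with between-group eigenvalue share
*s_a* and back-mapped loading vector *v_a*, the contribution of character
*c* is ``sum_a s_a * v_ac^2`` normalized over characters to sum to 1.

``find_clusters`` mirrors the exploratory cluster search (k-means on PCA
scores, scored by BIC), and ``xval_dapc`` selects the number of PCs to
retain by stratified cross-validation, minimizing the root mean squared
error of 1 - assignment success over replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from phylodisp.errors import ValidationError

_RANK_TOL = 1e-9


class _DapcFit:
    """Fitted centering/scaling + PCA rotation + LDA, able to predict."""

    def __init__(self, X: pd.DataFrame, groups: pd.Series, n_pcs: int, scale: bool):
        self.columns = list(X.columns)
        A = X.to_numpy(dtype=float)
        self.mean_ = A.mean(axis=0)
        A = A - self.mean_
        if scale:
            sd = A.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            self.sd_ = sd
            A = A / sd
        else:
            self.sd_ = None
        u, s, vt = np.linalg.svd(A, full_matrices=False)
        rank = int(np.sum(s > _RANK_TOL * s[0])) if s.size else 0
        if n_pcs > rank:
            raise ValidationError(f"n_pcs={n_pcs} exceeds data rank {rank}")
        self.rank_ = rank
        self.rotation_ = vt[:n_pcs].T  # p x n_pcs
        self.n_pcs = n_pcs
        scores = A @ self.rotation_
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.fit(scores, groups.to_numpy())
        self.classes_ = list(self.lda_.classes_)

    def _scores(self, X: pd.DataFrame) -> np.ndarray:
        A = X[self.columns].to_numpy(dtype=float) - self.mean_
        if self.sd_ is not None:
            A = A / self.sd_
        return A @ self.rotation_

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.lda_.transform(self._scores(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.lda_.predict(self._scores(X))


@dataclass
class DapcResult:
    """DAPC output: coordinates, centroids and per-character contributions."""

    n_pcs_retained: int
    n_axes: int
    coordinates: pd.DataFrame  # rows x discriminant axes
    centroids: pd.DataFrame  # groups x discriminant axes
    loadings: pd.DataFrame  # retained PCs x axes
    variable_contributions: pd.Series  # per character, sums to 1
    explained_ratio: np.ndarray  # between-group eigenvalue share per axis
    assignment_success: float  # resubstitution success, for reference
    fit: _DapcFit


def _validate_groups(groups: pd.Series, min_size: int = 2) -> None:
    counts = groups.value_counts()
    small = counts[counts < min_size]
    if len(counts) < 2:
        raise ValidationError("need >= 2 groups")
    if not small.empty:
        raise ValidationError(f"groups with < {min_size} rows: {list(small.index)}")


def dapc(
    data: pd.DataFrame, groups: pd.Series, n_pcs: int, scale: bool = False
) -> DapcResult:
    """Fit a DAPC with ``n_pcs`` retained principal components.

    ``data`` is rows (tribes) x variables (characters); ``groups`` maps rows
    to lineage labels.  The number of discriminant axes is
    ``min(#groups - 1, n_pcs)``.
    """
    if n_pcs < 1:
        raise ValidationError("n_pcs must be >= 1")
    groups = groups.reindex(data.index)
    if groups.isna().any():
        raise ValidationError("every row needs a group label")
    _validate_groups(groups)
    fit = _DapcFit(data, groups, n_pcs, scale)
    coords = fit.transform(data)
    axes = coords.shape[1]
    axis_names = [f"LD{i + 1}" for i in range(axes)]
    coordinates = pd.DataFrame(coords, index=data.index, columns=axis_names)
    centroids = coordinates.groupby(groups).mean()
    # LDA scalings live in PC space; back-map through the PCA rotation.
    w = fit.lda_.scalings_[:, :axes]  # n_pcs x axes
    loadings = pd.DataFrame(w, columns=axis_names)
    v = fit.rotation_ @ w  # p x axes
    share = np.asarray(fit.lda_.explained_variance_ratio_[:axes], dtype=float)
    if share.sum() <= 0:
        share = np.full(axes, 1.0 / axes)
    contrib = (v**2) @ (share / share.sum())
    contrib = contrib / contrib.sum()
    success = float(np.mean(fit.predict(data) == groups.to_numpy()))
    return DapcResult(
        n_pcs_retained=n_pcs,
        n_axes=axes,
        coordinates=coordinates,
        centroids=centroids,
        loadings=loadings,
        variable_contributions=pd.Series(contrib, index=data.columns, name="contribution"),
        explained_ratio=share,
        assignment_success=success,
        fit=fit,
    )


def find_clusters(
    data: pd.DataFrame, k_max: int, seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """K-means cluster search on PCA scores, scored by BIC.

    For each k in 1..k_max: k-means on the full set of PCA scores;
    BIC = n * log(WSS / n) + k * log(n).  The curve is returned without an
    automatic choice, since a flat or monotone curve means no defensible
    grouping.
    """
    n = len(data)
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be < n rows={n}")
    A = data.to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    scores = u * s  # all PCs: distances are preserved
    rows = []
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
            km.fit(scores)
            wss = float(km.inertia_)
        bic = n * np.log(wss / n) + k * np.log(n)
        rows.append((k, wss, bic))
    return pd.DataFrame(rows, columns=["k", "wss", "bic"])


def default_retention_grid(n_rows: int, n_vars: int, holdout: float = 0.1) -> list[int]:
    """<= 20 roughly even retention levels in 1..min(train size - 1, #vars)."""
    upper = min(int(np.floor(n_rows * (1 - holdout))) - 1, n_vars)
    upper = max(upper, 1)
    if upper <= 20:
        return list(range(1, upper + 1))
    grid = np.unique(np.linspace(1, upper, 20).round().astype(int))
    return [int(g) for g in grid]


def xval_dapc(
    data: pd.DataFrame,
    groups: pd.Series,
    retention_grid: list[int] | None = None,
    n_rep: int = 1000,
    holdout: float = 0.1,
    seed: int = 0,
    scale: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Cross-validated choice of the number of PCs to retain.

    Stratified random splits hold out ``holdout`` of each group per
    replicate; for each retention level the DAPC is refit on the training
    rows and assignment success measured on the held-out rows.  The score
    per level is the RMSE of (1 - success) over replicates; the best level
    is the argmin, with ties broken toward fewer PCs.
    """
    groups = groups.reindex(data.index)
    _validate_groups(groups, min_size=3)
    if retention_grid is None:
        retention_grid = default_retention_grid(len(data), data.shape[1], holdout)
    rng = np.random.default_rng(seed)
    by_group = {g: np.array(idx) for g, idx in groups.groupby(groups).groups.items()}
    err: dict[int, list[float]] = {lvl: [] for lvl in retention_grid}
    skipped: set[int] = set()
    for _ in range(n_rep):
        test_rows: list = []
        for g, idx in by_group.items():
            n_hold = max(1, int(round(holdout * len(idx))))
            if len(idx) - n_hold < 2:
                raise ValidationError(f"group {g!r} too small for holdout={holdout}")
            test_rows.extend(rng.choice(idx, size=n_hold, replace=False))
        test_rows = list(test_rows)
        train = data.drop(index=test_rows)
        test = data.loc[test_rows]
        g_train = groups.drop(index=test_rows)
        g_test = groups.loc[test_rows]
        for lvl in retention_grid:
            try:
                fit = _DapcFit(train, g_train, lvl, scale)
            except ValidationError:
                skipped.add(lvl)
                continue
            success = float(np.mean(fit.predict(test) == g_test.to_numpy()))
            err[lvl].append(1.0 - success)
    if skipped:
        warnings.warn(f"retention levels above training rank skipped: {sorted(skipped)}")
    rows = []
    for lvl in retention_grid:
        if err[lvl]:
            e = np.array(err[lvl])
            rows.append((lvl, float(np.sqrt(np.mean(e**2))), float(1 - e.mean()), len(e)))
    cv_table = pd.DataFrame(rows, columns=["n_pcs", "rmse", "mean_success", "n_rep"])
    best = int(cv_table.loc[cv_table["rmse"].idxmin(), "n_pcs"])
    # tie-break toward fewer PCs (parsimony)
    min_rmse = cv_table["rmse"].min()
    best = int(cv_table.loc[cv_table["rmse"] <= min_rmse, "n_pcs"].min())
    return best, cv_table
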