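"""End-to-end orchestration: disparity -> frequencies -> signal -> group
tests -> DAPC -> ages/covariates, driven by a YAML config, with one log
line per stage and deterministic, seed-stamped CSV outputs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import phylodisp
from phylodisp.ages import (
    TribeAges,
    calibrate_and_impute,
    extract_ages,
    genome_size_variation,
    summarize_ages,
)
from phylodisp.comparative import (
    lineage_rank_tests,
    morans_i,
    phyl_anova,
    pic_correlation,
)
from phylodisp.core_data import CharacterScheme, TaxonomyTable, aggregate_to_tribes, read_morphomatrix
from phylodisp.dapc import dapc, find_clusters, xval_dapc
from phylodisp.disparity import (
    lineage_state_frequencies,
    tribal_disparity_direct,
    tribal_disparity_from_genera,
)
from phylodisp.errors import DegenerateDataError, PhylodispError, ValidationError
from phylodisp.trees import prune_to_tribes, read_newick

log = logging.getLogger("phylodisp")


@dataclass
class RunConfig:
    """Paths and test settings for a full pipeline run."""

    morphomatrix: str
    scheme: str
    genus_taxonomy: str
    tribe_table: str
    tree: str
    outdir: str
    genome_sizes: str | None = None
    external_crown_ages: str | None = None  # CSV tribe,crown for calibration
    lineage_scheme: str = "lineage"
    n_perm: int = 999
    n_sim: int = 1000
    alpha: float = 0.05
    seed: int = 0
    dapc_n_rep: int = 200
    dapc_holdout: float = 0.1
    merge_age_groups: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        for key in ("morphomatrix", "scheme", "genus_taxonomy", "tribe_table", "tree"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise ValidationError(f"config {key}: file not found: {p}")
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PhylodispError as exc:
                raise PhylodispError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_all(cfg: RunConfig) -> dict[str, str]:
    """Run every stage and write the report bundle to ``cfg.outdir``.

    Returns a map of artifact name to file path.  All stochastic stages are
    driven by ``cfg.seed``; rerunning with the same config reproduces every
    statistic bitwise.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=index)
        paths[name] = str(p)

    scheme = CharacterScheme.from_yaml(cfg.scheme)
    matrix = read_morphomatrix(cfg.morphomatrix, scheme)
    tax = TaxonomyTable.from_csvs(cfg.genus_taxonomy, cfg.tribe_table, cfg.genome_sizes)
    tree = read_newick(cfg.tree)
    log.info(
        "inputs: %d genera x %d characters, %d tribes, %d tree tips, seed=%d",
        len(matrix.genera), len(scheme), len(tax.tribes), tree.n_tips, cfg.seed,
    )

    # -- disparity ---------------------------------------------------------
    tsm = _stage("aggregate")(aggregate_to_tribes)(matrix, tax)
    direct = _stage("disparity")(tribal_disparity_direct)(tsm)
    from_genera = tribal_disparity_from_genera(matrix, tax)
    save("disparity_direct", direct.values)
    save("disparity_from_genera", from_genera.values)
    tidy = pd.concat([direct.to_tidy(), from_genera.to_tidy()])
    save("disparity_tidy", tidy, index=False)

    # -- lineage frequencies ----------------------------------------------
    freqs = _stage("frequencies")(lineage_state_frequencies)(tsm, tax, cfg.lineage_scheme)
    save("lineage_frequencies", freqs.frequencies)
    save("lineage_pairwise_differences", freqs.pairwise, index=False)

    # -- phylogenetic signal ----------------------------------------------
    tribal_tree = _stage("prune")(prune_to_tribes)(tree, tax.genus_to_tribe)
    signal_rows = []
    mean_series = direct.mean_disparity
    columns = list(direct.values.columns) + ["mean_disparity"]
    for i, char_id in enumerate(columns):
        vals = mean_series if char_id == "mean_disparity" else direct.values[char_id]
        vals = vals.dropna()
        tips = [t for t in tribal_tree.tip_labels if t in vals.index]
        if len(tips) < 4 or vals[tips].nunique() < 2:
            continue
        sub = tribal_tree.extract(tips) if len(tips) < tribal_tree.n_tips else tribal_tree
        res = morans_i(vals, sub, n_perm=cfg.n_perm, seed=cfg.seed + i, name=char_id)
        signal_rows.append(
            (char_id, res.morans_i, res.expected_null, res.p_value, res.n_perm, res.seed)
        )
    signal = pd.DataFrame(
        signal_rows, columns=["character", "morans_i", "expected_null", "p", "n_perm", "seed"]
    )
    log.info("stage %-12s done (%d characters)", "signal", len(signal))
    save("morans_i", signal, index=False)

    # -- group tests: WGD / rate shift / 4-level composites ---------------
    trait = mean_series.reindex(tribal_tree.tip_labels)
    anova_rows = []
    groupings = {
        "wgd": pd.Series({t: ("wgd" if tax.wgd.get(t) else "no_wgd") for t in tax.tribes}),
        "rate_shift": pd.Series(
            {t: ("shift" if tax.rate_shift.get(t) else "no_shift") for t in tax.tribes}
        ),
    }
    for gi, (gname, groups) in enumerate(groupings.items()):
        try:
            res = phyl_anova(
                tribal_tree, groups, trait, n_sim=cfg.n_sim, seed=cfg.seed + 100 + gi
            )
        except (ValidationError, DegenerateDataError) as exc:
            log.warning("phylANOVA %s skipped: %s", gname, exc)
            continue
        anova_rows.append((gname, "mean_disparity", res.f_obs, res.p_phyl, res.p_standard,
                           res.n_sim, res.seed))
    # diversification rates across the WGD x shift 4-level grouping
    if tax.covariates is not None and "net_div" in tax.covariates:
        combo = pd.Series(
            {
                t: f"{'wgd' if tax.wgd.get(t) else 'no_wgd'}+"
                f"{'shift' if tax.rate_shift.get(t) else 'no_shift'}"
                for t in tax.tribes
            }
        )
        for col in ("speciation", "extinction", "net_div"):
            vals = tax.covariates[col].reindex(tribal_tree.tip_labels)
            try:
                res = phyl_anova(
                    tribal_tree, combo, vals, n_sim=cfg.n_sim, seed=cfg.seed + 200
                )
                anova_rows.append(("wgd_x_shift", col, res.f_obs, res.p_phyl,
                                   res.p_standard, res.n_sim, res.seed))
            except (ValidationError, DegenerateDataError) as exc:
                log.warning("phylANOVA wgd_x_shift %s skipped: %s", col, exc)
    anova = pd.DataFrame(
        anova_rows, columns=["grouping", "trait", "f_obs", "p_phyl", "p_standard", "n_sim", "seed"]
    )
    log.info("stage %-12s done (%d tests)", "groups", len(anova))
    save("phyl_anova", anova, index=False)

    # -- ages and covariates ----------------------------------------------
    ages = _stage("ages")(extract_ages)(
        tree, tax.genus_to_tribe, merge_groups=cfg.merge_age_groups or None
    )
    if cfg.external_crown_ages:
        ext = pd.read_csv(cfg.external_crown_ages, index_col="tribe")["crown"]
        model, ages = calibrate_and_impute(ages, ext)
        paths["calibration"] = str(outdir / "calibration.json")
        Path(paths["calibration"]).write_text(
            json.dumps(
                {
                    "slope": model.slope,
                    "intercept": model.intercept,
                    "spearman_rho": model.spearman_rho,
                    "spearman_p": model.spearman_p,
                    "n_pairs": model.n_pairs,
                },
                indent=2,
            )
        )
    ages.to_csv(outdir / "tribe_ages.csv")
    paths["tribe_ages"] = str(outdir / "tribe_ages.csv")
    save("ages_summary", summarize_ages(ages))

    # -- PIC correlations of tribal covariates ----------------------------
    cov = pd.DataFrame({"mean_disparity": mean_series})
    cov["stem_age"] = ages.table["stem"]
    cov["crown_age"] = ages.table["crown"]
    cov["lag"] = ages.table["lag"]
    if tax.covariates is not None:
        for col in tax.covariates.columns:
            cov[col] = tax.covariates[col]
    if tax.genome_sizes:
        cov["genome_size_cv"] = genome_size_variation(tax.genome_sizes)
    pic_rows = []
    cols = list(cov.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = cov[[a, b]].dropna()
            tips = [t for t in tribal_tree.tip_labels if t in pair.index]
            if len(tips) < 5:
                continue
            sub = tribal_tree.extract(tips) if len(tips) < tribal_tree.n_tips else tribal_tree
            try:
                r, p = pic_correlation(sub, pair.loc[tips, a], pair.loc[tips, b])
            except DegenerateDataError:
                continue
            pic_rows.append((a, b, r, p, len(tips)))
    pic_table = pd.DataFrame(pic_rows, columns=["x", "y", "r", "p", "n_tribes"])
    log.info("stage %-12s done (%d pairs)", "pic", len(pic_table))
    save("pic_correlations", pic_table, index=False)

    # -- lineage rank tests ------------------------------------------------
    lineage = pd.Series({t: tax.lineage_of(t, cfg.lineage_scheme) for t in tax.tribes})
    kw_rows = []
    for col in cov.columns:
        try:
            res = lineage_rank_tests(cov[col], lineage, alpha=cfg.alpha)
        except (ValidationError, DegenerateDataError) as exc:
            log.warning("rank test %s skipped: %s", col, exc)
            continue
        kw_rows.append((col, res.kw_statistic, res.kw_p))
        if res.pairwise_p is not None:
            save(f"wilcoxon_{col}", res.pairwise_p)
    save("kruskal_wallis", pd.DataFrame(kw_rows, columns=["trait", "H", "p"]), index=False)

    # -- DAPC ---------------------------------------------------------------
    dap_data = direct.values.dropna(axis=1, how="any").dropna(axis=0, how="any")
    dap_groups = lineage.reindex(dap_data.index).dropna()
    # stratified cross-validation needs a few tribes per group; lineages
    # below that are excluded from the discriminant analysis
    counts = dap_groups.value_counts()
    usable = counts[counts >= 3].index
    if len(counts[counts < 3]):
        log.warning("DAPC: lineages with < 3 tribes excluded: %s",
                    sorted(counts[counts < 3].index))
    dap_groups = dap_groups[dap_groups.isin(usable)]
    dap_data = dap_data.loc[dap_groups.index]
    bic = _stage("find_clusters")(find_clusters)(
        dap_data, k_max=min(10, len(dap_data) - 1), seed=cfg.seed
    )
    save("find_clusters_bic", bic, index=False)
    best = None
    if len(usable) >= 2:
        best, cv_table = _stage("xval_dapc")(xval_dapc)(
            dap_data, dap_groups, n_rep=cfg.dapc_n_rep, holdout=cfg.dapc_holdout, seed=cfg.seed
        )
        save("dapc_xval", cv_table, index=False)
        result = _stage("dapc")(dapc)(dap_data, dap_groups, n_pcs=best)
        save("dapc_coordinates", result.coordinates)
        save("dapc_centroids", result.centroids)
        save("dapc_contributions", result.variable_contributions.to_frame())
    else:
        log.warning("DAPC skipped: fewer than two usable lineages")

    manifest = {
        "package_version": phylodisp.__version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_sim": cfg.n_sim,
        "lineage_scheme": cfg.lineage_scheme,
        "dapc_n_pcs": best,
        "inputs": {
            "n_genera": len(matrix.genera),
            "n_characters": len(scheme),
            "n_states": scheme.n_states,
            "n_tribes": len(tax.tribes),
            "n_tree_tips": tree.n_tips,
        },
        "artifacts": sorted(paths),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    paths["run_manifest"] = str(outdir / "run_manifest.json")
    return paths
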