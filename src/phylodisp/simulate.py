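"""Synthetic data with the statistical structure the analysis assumes.

The generator produces the three inputs every pipeline stage consumes:

* a dated, ultrametric genus-level tree in which tribes are monophyletic
  clades and lineages are deeper monophyletic clades (a birth-death
  backbone over tribes, rescaled to a fixed root age, with random
  ultrametric within-tribe subtrees);
* a taxonomy table with lineage assignment, WGD (mesopolyploidization) and
  rate-shift flags, species/genus richness and genome-size covariates;
* a morphological matrix of unordered multistate characters evolved under
  a symmetric Mk process along the tree, with genus-level polymorphism
  (the union over a few pseudo-species simulated along each terminal
  branch), optional planted lineage-private states, optional clade-specific
  rate elevation in WGD-flagged tribes (standing in for the morphological
  consequences of genome duplication), and optional missing-data masking.

Defaults mirror the shape of the empirical study system: 51 tribes in 3
lineages, ~350 genera, 37 characters with 111 states in total, 11
WGD-flagged and 9 rate-shift-flagged tribes (both restricted to the two
larger lineages), and no missing cells (the empirical matrix was scored for
all genera).  The WGD rate multiplier defaults to 1 (no planted effect);
power experiments raise it explicitly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from phylodisp.core_data import (
    Character,
    CharacterScheme,
    MorphoMatrix,
    TaxonomyTable,
    write_morphomatrix,
)
from phylodisp.errors import ValidationError
from phylodisp.trees import DatedTree

# 37 characters / 111 states: 12 binary, 15 three-state, 8 four-state,
# 2 five-state (12*2 + 15*3 + 8*4 + 2*5 = 111).
DEFAULT_STATE_COUNTS: tuple[int, ...] = (2,) * 12 + (3,) * 15 + (4,) * 8 + (5,) * 2


@dataclass
class PrivateState:
    """A state planted only within one lineage at a given tribal prevalence.

    The reserved state (the last state of ``character_id``) is excluded
    from the Mk simulation and added afterwards to one genus in a fixed
    fraction of the lineage's tribes, so the planted lineage frequency is
    known exactly.
    """

    character_id: str
    lineage: str
    prevalence: float


@dataclass
class SimConfig:
    """Configuration for one synthetic data set (all rates per my)."""

    seed: int = 0
    n_tribes: int = 51
    n_lineages: int = 3
    mean_genera_per_tribe: float = 6.9
    birth_rate: float = 0.3
    death_rate: float = 0.1
    root_age: float = 32.0
    state_counts: tuple[int, ...] = DEFAULT_STATE_COUNTS
    mk_rate: float = 0.03
    n_wgd_tribes: int | None = None  # default: the study fraction 11/51
    wgd_rate_multiplier: float = 1.0
    n_rate_shift_tribes: int | None = None  # default: the study fraction 9/51
    # Monotone power transform applied to backbone node ages (age ->
    # root_age * (age/root_age)**gamma).  Conditioned birth-death trees
    # rescaled to a fixed root age put most splits near the present; the
    # empirical chronogram instead shows tribal stem ages of ~15 my and
    # crown ages of ~10 my under a ~32-my root.  gamma = 0.3 deepens the
    # backbone to that scale; 1.0 restores raw birth-death ages.
    node_age_power: float = 0.3
    lineage_private_states: list[PrivateState] = field(default_factory=list)
    missing_fraction: float = 0.0
    pseudo_species: int = 3
    retry_cap: int = 100

    def __post_init__(self) -> None:
        if self.birth_rate <= self.death_rate or self.death_rate < 0:
            raise ValidationError("need birth_rate > death_rate >= 0")
        if self.wgd_rate_multiplier < 1:
            raise ValidationError("WGD rate multiplier must be >= 1")
        if not (0 <= self.missing_fraction < 1):
            raise ValidationError("missing_fraction must be in [0, 1)")
        if any(k < 2 for k in self.state_counts):
            raise ValidationError("every character needs >= 2 states")
        if self.n_wgd_tribes is None:
            self.n_wgd_tribes = max(2, round(self.n_tribes * 11 / 51))
        if self.n_rate_shift_tribes is None:
            self.n_rate_shift_tribes = max(2, round(self.n_tribes * 9 / 51))

    def scheme(self) -> CharacterScheme:
        """Character catalogue implied by ``state_counts`` (categories A-F
        assigned round-robin)."""
        chars = []
        for i, k in enumerate(self.state_counts, start=1):
            cid = f"C{i:02d}"
            chars.append(
                Character(
                    id=cid,
                    category="ABCDEF"[(i - 1) % 6],
                    label=f"synthetic character {i}",
                    states=tuple(f"{cid}-{j}" for j in range(1, k + 1)),
                )
            )
        return CharacterScheme(chars)


# ---------------------------------------------------------------------------
# tree simulation


def _rescale(tree: dendropy.Tree, factor: float) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor


def _backbone(cfg: SimConfig, rng: np.random.Generator) -> dendropy.Tree:
    """Birth-death tree over tribes, conditioned on tip count, rescaled so
    the root age equals ``cfg.root_age``."""
    from dendropy.simulate import treesim

    last_err: Exception | None = None
    for _ in range(cfg.retry_cap):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=cfg.birth_rate,
                death_rate=cfg.death_rate,
                num_extant_tips=cfg.n_tribes,
                rng=random.Random(int(rng.integers(2**31))),
            )
            break
        except Exception as exc:  # all lineages extinct in this replicate
            last_err = exc
    else:
        raise ValidationError(f"birth-death simulation failed {cfg.retry_cap} times: {last_err}")
    # the simulator stops at the n-th speciation, leaving a zero-age node;
    # extend all terminal branches by a waiting time to the next event so
    # the youngest split has positive age, then rescale to the root age
    extension = rng.exponential(1.0 / (cfg.n_tribes * (cfg.birth_rate + cfg.death_rate)))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extension
    # root-to-tip depth of the (ultrametric) extant tree
    tree.calc_node_root_distances()
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    _rescale(tree, cfg.root_age / depth)
    if cfg.node_age_power != 1.0:
        # deepen node ages toward the empirical tribal age scale while
        # preserving the parent-older-than-child ordering
        tree.calc_node_root_distances()
        new_depth: dict[int, float] = {}
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                new_depth[id(nd)] = cfg.root_age
            else:
                age = cfg.root_age - nd.root_distance
                new_age = cfg.root_age * (age / cfg.root_age) ** cfg.node_age_power
                new_depth[id(nd)] = cfg.root_age - new_age
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = new_depth[id(nd)] - new_depth[id(nd.parent_node)]
    return tree


def _random_ultrametric_subtree(
    labels: list[str], crown: float, rng: np.random.Generator
) -> str:
    """Newick (no trailing ';') of a random ultrametric tree over ``labels``
    with crown age ``crown``: sequential random joins at increasing ages."""
    n = len(labels)
    ages = np.sort(rng.uniform(0.05 * crown, crown, size=n - 1))
    ages[-1] = crown
    clades = [(lab, 0.0) for lab in labels]  # (newick, age of clade root)
    for a in ages:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        nj, aj = clades.pop(j)
        ni, ai = clades.pop(i)
        merged = f"({ni}:{a - ai:.10f},{nj}:{a - aj:.10f})"
        clades.append((merged, float(a)))
    return clades[0][0]


def _partition_lineages(
    tree: dendropy.Tree, n_lineages: int
) -> dict[str, str]:
    """Split the backbone into ``n_lineages`` monophyletic groups by
    repeatedly dividing the largest clade at its root."""
    clades = [tree.seed_node]
    while len(clades) < n_lineages:
        clades.sort(key=lambda nd: -len(nd.leaf_nodes()))
        big = clades.pop(0)
        kids = big.child_nodes()
        if not kids:
            raise ValidationError("cannot partition tree into that many lineages")
        clades.extend(kids)
    # stable naming: order groups by their alphabetically first tip
    clades.sort(key=lambda nd: min(l.taxon.label for l in nd.leaf_iter()))
    mapping: dict[str, str] = {}
    for i, nd in enumerate(clades, start=1):
        for leaf in nd.leaf_iter():
            mapping[leaf.taxon.label] = f"L{i}"
    return mapping


def simulate_tree(cfg: SimConfig) -> tuple[DatedTree, TaxonomyTable]:
    """Simulate the dated genus-level tree and the matching taxonomy.

    Tribes (and lineages) are monophyletic by construction.  WGD and
    rate-shift flags are drawn only within the two largest lineages,
    matching the empirical pattern that mesopolyploidizations and rate
    shifts are restricted to lineages I and II.
    """
    rng = np.random.default_rng(cfg.seed)
    backbone = _backbone(cfg, rng)
    tribe_names = [f"Tribe{i:02d}" for i in range(1, cfg.n_tribes + 1)]
    leaves = backbone.leaf_nodes()
    rng.shuffle(leaves)  # decouple tribe numbering from simulation order
    for leaf, name in zip(leaves, tribe_names):
        leaf.taxon.label = name
    lineage_of_tribe = _partition_lineages(backbone, cfg.n_lineages)

    # genera per tribe: zero-truncated geometric, mean ~ cfg.mean_genera_per_tribe
    p = 1.0 / cfg.mean_genera_per_tribe
    n_genera = rng.geometric(p, size=cfg.n_tribes)

    backbone.calc_node_root_distances()
    genus_to_tribe: dict[str, str | None] = {}
    newick_parts: dict[str, str] = {}
    crown_true: dict[str, float] = {}
    for leaf in backbone.leaf_node_iter():
        tribe = leaf.taxon.label
        g = int(n_genera[tribe_names.index(tribe)])
        genera = [f"{tribe}_g{j:02d}" for j in range(1, g + 1)]
        for ge in genera:
            genus_to_tribe[ge] = tribe
        stem_branch_parent_age = cfg.root_age - (leaf.root_distance - leaf.edge.length)
        if g == 1:
            newick_parts[tribe] = genera[0]
            crown_true[tribe] = np.nan
        else:
            # crown/stem ratio centred on the empirical ~0.66 (mean tribal
            # lag-phase of ~5 my on a ~15-my stem age)
            crown = float(rng.uniform(0.4, 0.9) * stem_branch_parent_age)
            newick_parts[tribe] = _random_ultrametric_subtree(genera, crown, rng)
            crown_true[tribe] = crown

    # splice tribe subtrees into the backbone newick; the pendant runs from
    # the tribe's stem node down to its crown node (or single genus tip)
    for leaf in backbone.leaf_node_iter():
        tribe = leaf.taxon.label
        crown = crown_true[tribe]
        stem_parent_age = cfg.root_age - (leaf.root_distance - leaf.edge.length)
        leaf.taxon.label = f"SLOT{tribe}SLOT"
        leaf.edge.length = stem_parent_age - (0.0 if np.isnan(crown) else crown)
    newick = backbone.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    for tribe, part in newick_parts.items():
        newick = newick.replace(f"SLOT{tribe}SLOT", part)
    genus_tree = DatedTree.from_newick(newick)

    # flags: restricted to the two largest lineages
    lineage_sizes = pd.Series(lineage_of_tribe).value_counts()
    eligible_lineages = list(lineage_sizes.index[: max(2, 1)][:2])
    eligible = sorted(t for t, l in lineage_of_tribe.items() if l in eligible_lineages)
    wgd_tribes = sorted(rng.choice(eligible, size=min(cfg.n_wgd_tribes, len(eligible)), replace=False))
    shift_tribes = sorted(
        rng.choice(eligible, size=min(cfg.n_rate_shift_tribes, len(eligible)), replace=False)
    )

    # covariates: species richness from per-genus geometric draws; crude
    # net-diversification estimate from richness and stem age
    n_species = {}
    for i, tribe in enumerate(tribe_names):
        n_species[tribe] = int(rng.geometric(1 / 11.0, size=int(n_genera[i])).sum())
    cov = pd.DataFrame(
        {
            "n_species": pd.Series(n_species),
            "n_genera": pd.Series({t: int(n_genera[i]) for i, t in enumerate(tribe_names)}),
        }
    )
    cov.index.name = "tribe"
    net_div: dict[str, float] = {}
    for tribe in tribe_names:
        # standard crude estimator log(n)/t on the tribe's stem age scale
        net_div[tribe] = float(np.log(max(cov.loc[tribe, "n_species"], 2)) / cfg.root_age * 2)
    cov["net_div"] = pd.Series(net_div)
    cov["speciation"] = cov["net_div"] * 1.5
    cov["extinction"] = cov["net_div"] * 0.5

    genome_sizes: dict[str, list[float]] = {}
    for tribe in tribe_names:
        n_est = int(rng.poisson(4))
        if n_est:
            base = 0.5 * (1.5 if tribe in wgd_tribes else 1.0)
            genome_sizes[tribe] = [
                float(v) for v in np.exp(rng.normal(np.log(base), 0.4, size=n_est))
            ]

    tax = TaxonomyTable(
        genus_to_tribe=genus_to_tribe,
        lineage_schemes={"lineage": dict(sorted(lineage_of_tribe.items()))},
        wgd={t: (t in wgd_tribes) for t in tribe_names},
        rate_shift={t: (t in shift_tribes) for t in tribe_names},
        covariates=cov,
        genome_sizes=genome_sizes,
    )
    return genus_tree, tax


# ---------------------------------------------------------------------------
# character simulation


def _mk_transition(states: np.ndarray, k: np.ndarray, q: np.ndarray, t: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One symmetric-Mk step for all characters at once.

    For a k-state symmetric model with total leaving rate q, the transition
    probability over time t is p(stay) = 1/k + (k-1)/k * exp(-q t k/(k-1));
    a change lands uniformly on one of the other k-1 states.
    """
    p_stay = 1.0 / k + (k - 1.0) / k * np.exp(-q * t * k / (k - 1.0))
    u = rng.random(states.size)
    out = states.copy()
    change = u >= p_stay
    if np.any(change):
        jump = rng.integers(0, (k - 1)[change].astype(int))
        new = jump + (jump >= states[change])  # uniform over states != current
        out[change] = new
    return out


def simulate_characters(tree: DatedTree, cfg: SimConfig, tax: TaxonomyTable) -> MorphoMatrix:
    """Evolve the multistate matrix along the genus tree under symmetric Mk.

    Branches inside a WGD-flagged tribe (its stem branch and everything
    below) evolve at ``mk_rate * wgd_rate_multiplier``, elevating realized
    state diversity there.  Each genus cell is the union over
    ``pseudo_species`` independent realizations of its terminal branch,
    which is what produces polymorphic genus scoring.  States reserved for
    planted lineage-private occurrence are excluded from the Mk state space
    and inserted afterwards at their configured tribal prevalence.
    Finally, cells are masked to missing at ``missing_fraction``.
    """
    scheme = cfg.scheme()
    rng = np.random.default_rng(cfg.seed + 1)
    k_full = np.array([c.k for c in scheme], dtype=float)
    q = np.full(len(scheme), cfg.mk_rate, dtype=float)

    reserved: dict[str, PrivateState] = {ps.character_id: ps for ps in cfg.lineage_private_states}
    # Mk runs on k-1 states for characters carrying a planted private state
    k_sim = k_full.copy()
    for i, c in enumerate(scheme):
        if c.id in reserved:
            if c.k < 3:
                raise ValidationError(
                    f"character {c.id!r}: need >= 3 states to reserve one for planting"
                )
            k_sim[i] = c.k - 1

    wgd_tribes = {t for t, flag in tax.wgd.items() if flag}

    # tribe membership of every node (None if the clade spans tribes)
    node_tribe: dict[int, str | None] = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            node_tribe[id(nd)] = tax.genus_to_tribe.get(nd.taxon.label)
        else:
            tribes = {node_tribe[id(c)] for c in nd.child_nodes()}
            node_tribe[id(nd)] = tribes.pop() if len(tribes) == 1 else None

    def branch_rate(nd) -> np.ndarray:
        mult = cfg.wgd_rate_multiplier if node_tribe[id(nd)] in wgd_tribes else 1.0
        return q * mult

    n_char = len(scheme)
    node_state: dict[int, np.ndarray] = {}
    cells: dict[tuple[str, str], set[str]] = {}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            node_state[id(nd)] = rng.integers(0, k_sim.astype(int))
            continue
        parent_state = node_state[id(nd.parent_node)]
        if not nd.is_leaf():
            node_state[id(nd)] = _mk_transition(
                parent_state, k_sim, branch_rate(nd), nd.edge.length, rng
            )
            continue
        genus = nd.taxon.label
        union = [set() for _ in range(n_char)]
        for _ in range(cfg.pseudo_species):
            tip_state = _mk_transition(parent_state, k_sim, branch_rate(nd), nd.edge.length, rng)
            for ci in range(n_char):
                union[ci].add(int(tip_state[ci]))
        for ci, c in enumerate(scheme.characters):
            cells[(genus, c.id)] = {c.states[s] for s in union[ci]}

    # plant lineage-private states at exact tribal prevalence
    for ps in cfg.lineage_private_states:
        char = scheme[ps.character_id]
        private_state = char.states[-1]
        tribes = tax.tribes_of_lineage(ps.lineage)
        n_present = int(round(ps.prevalence * len(tribes)))
        chosen = sorted(rng.choice(tribes, size=n_present, replace=False))
        for tribe in chosen:
            genera = sorted(tax.genera_of(tribe))
            carrier = genera[int(rng.integers(len(genera)))]
            cells[(carrier, char.id)].add(private_state)

    if cfg.missing_fraction > 0:
        keys = sorted(cells)
        mask = rng.random(len(keys)) < cfg.missing_fraction
        for key, drop in zip(keys, mask):
            if drop:
                cells[key] = set()

    genera = sorted(tax.genus_to_tribe)
    return MorphoMatrix(scheme, genera, cells)


# ---------------------------------------------------------------------------
# fixture export


def make_fixture(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Write a complete synthetic input set to ``outdir``.

    Files: ``morphomatrix.csv``, ``scheme.yaml``, ``genus_taxonomy.csv``,
    ``tribes.csv``, ``genome_sizes.csv``, ``tree_genera.nwk`` and
    ``manifest.json`` (config echo + seed).  Output is byte-identical for
    identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, tax = simulate_tree(cfg)
    matrix = simulate_characters(tree, cfg, tax)
    paths = {
        "morphomatrix": outdir / "morphomatrix.csv",
        "scheme": outdir / "scheme.yaml",
        "genus_taxonomy": outdir / "genus_taxonomy.csv",
        "tribes": outdir / "tribes.csv",
        "genome_sizes": outdir / "genome_sizes.csv",
        "tree": outdir / "tree_genera.nwk",
        "manifest": outdir / "manifest.json",
    }
    write_morphomatrix(matrix, paths["morphomatrix"])
    cfg.scheme().to_yaml(paths["scheme"])
    tax.to_csvs(paths["genus_taxonomy"], paths["tribes"])
    rows = [
        {"tribe": t, "genome_size_pg": v}
        for t in sorted(tax.genome_sizes)
        for v in tax.genome_sizes[t]
    ]
    pd.DataFrame(rows, columns=["tribe", "genome_size_pg"]).to_csv(
        paths["genome_sizes"], index=False
    )
    tree.write(paths["tree"])
    manifest = {"config": asdict(cfg), "n_genera": len(matrix.genera)}
    manifest["config"]["state_counts"] = list(cfg.state_counts)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
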