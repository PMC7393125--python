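# phylodisp

Morphological disparity analysis on dated phylogenies, built for
family-wide data sets of discrete characters scored at the genus level —
the motivating system being the mustard family (Brassicaceae) with its 51
tribes, three major evolutionary lineages, and repeated whole-genome
duplications (WGDs).

## What it computes

**Disparity.** For a character with `k` states, the disparity of a taxon is
the fraction of states realized there:

    D(taxon, c) = |states observed| / k,      1/k <= D <= 1

Tribal disparity comes in two aggregation routes: *direct* (the union of
the member genera's states, scored on the tribal presence/absence matrix)
and *from genera* (the mean of member-genus disparities). The union can
only grow, so direct >= from-genera holds everywhere — the package enforces
this as an invariant.

**Comparative statistics** on a dated, ultrametric tribal tree:

- Moran's *I* phylogenetic signal with inverse-patristic-distance weights
  and a tip-permutation null (`E[I] = -1/(n-1)`);
- simulation-based phylogenetic ANOVA: the observed one-way *F* is referred
  to *F* values from Brownian-motion simulations on the tree
  (`p = (1 + #{F_sim >= F_obs}) / (n_sim + 1)`), with simulation-based
  post-hoc pairwise *t* tests and Bonferroni correction;
- Felsenstein's phylogenetically independent contrasts (PIC) and the
  through-origin contrast correlation;
- Kruskal–Wallis and pairwise Wilcoxon rank tests across lineages.

**DAPC** (discriminant analysis of principal components) of tribal
disparity with lineage priors: PCA, LDA on retained scores,
cross-validated choice of the number of PCs (lowest RMSE of assignment
failure over stratified 90/10 splits), per-character contributions via
back-mapped squared loadings, and a BIC-scored k-means cluster search.

**Clade ages.** Stem and crown group ages per tribe, the lag-phase
(stem - crown), cross-study calibration regression with imputation of
missing crown ages, genome-size variation (CV with a minimum of three
estimates), and WGD-rate arithmetic (WGDs per genus per 10 my).

**Synthetic data.** A generator producing dated trees with monophyletic
tribes and lineages, taxonomies with WGD/rate-shift flags and covariates,
and multistate matrices evolved under a symmetric Mk process — including
genus-level polymorphism, planted lineage-private states, and clade-specific
rate elevation standing in for WGD effects — so the entire pipeline is
testable without any external data.

## Worked example

```sh
python examples/01_simulate_and_disparity.py
```

```
simulated 91 genera in 20 tribes, 37 characters / 111 states
mean tribal disparity, direct:      0.782
mean tribal disparity, from genera: 0.537
direct >= from-genera everywhere:   True
characters with the highest mean disparity (most states realized per tribe):
  C09: 0.975
  C07: 0.950
  C05: 0.950
```

The direct value (0.782) exceeds the from-genera value (0.537) because
different genera within a tribe realize different states; the union credits
the tribe with all of them, the mean does not. Characters near 1.0 have
nearly all their states realized in most tribes.

```sh
python examples/03_group_tests.py
```

```
mean disparity, WGD tribes:    0.959 (n=6)
mean disparity, non-WGD tribes: 0.780
phylogenetic ANOVA: F = 15.72, p_phyl = 0.0020 (standard-ANOVA p = 0.0005)
```

Here the generator planted a fourfold character-evolution rate elevation in
WGD-flagged tribes; the phylogenetic ANOVA detects the resulting disparity
difference even against a Brownian null that absorbs shared ancestry.

The other examples cover phylogenetic signal (`02`), DAPC (`04`), and
ages/calibration/WGD arithmetic (`05`). A thin CLI wraps the same library
calls (`phylodisp simulate|disparity|signal|groups|dapc|ages|run-all`);
`run-all` executes the full pipeline from a YAML config and writes a
seed-stamped CSV bundle.

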