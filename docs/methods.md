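# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## The disparity statistic

Disparity is defined per character and taxon as the fraction of the
character's `k` states realized at that taxonomic level, bounded by `1/k`
(one state) and 1 (all states). It is a *range*-type disparity measure on
unordered multistate data; no distance- or variance-based morphospace
metrics are provided, by design.

Missing data convention: an empty cell means *unscored*, never "all states
absent". A genus unscored for a character is excluded from that
character's tribal union, mean, and frequency denominators. Mean disparity
per taxon is the unweighted mean over characters with data (invariant
characters are not excluded; characters missing in a taxon are dropped
from that taxon's mean only). Values are kept at full precision
internally; rounding to two decimals is presentation-only.

Two tribal aggregation routes are provided. *Direct* scores the
presence/absence union of the member genera; *from genera* averages the
member-genus values. Direct dominates from-genera pointwise because union
cardinality is at least the average cardinality; the test suite asserts
this on 1000 random matrices, and equality holds exactly for single-genus
tribes.

Lineage state frequencies use, as denominator, the number of the lineage's
tribes with the owning character scored — not all tribes — so missing data
do not deflate frequencies. Pairwise lineage differences are absolute
frequency differences per state.

## Moran's I

`I = (n/W) Σ_ij w_ij (x_i - x̄)(x_j - x̄) / Σ_i (x_i - x̄)²` with weights
`w_ij = 1 / patristic distance`, zero diagonal, row-standardized. This is
the standard proximity choice for phylogenetic autocorrelation; the weight
matrix is an explicit argument, so other proximities can be substituted.
The null is a tip-label permutation (default `n_perm = 999`); under
exchangeability `E[I] = -1/(n-1)` exactly (the suite verifies this by
exhaustive permutation on 5-tip trees). The two-sided p doubles the
smaller one-tailed add-one estimate, capped at 1, and is reproducible
given the seed. A constant trait is an error, not a zero. The
implementation was cross-checked against an independent reference
implementation (ape in R): both `pic` and Moran's I agree to printed
precision on a fixed 5-tip tree, frozen in the test suite.

## Phylogenetic ANOVA

The observed statistic is the ordinary one-way ANOVA F. The null
distribution comes from Brownian-motion simulations on the dated tree with
the rate set to the mean squared standardized contrast of the trait
(REML-like; note F is scale-invariant, so the rate estimate affects only
the simulated traits, not the calibration of the test). The p value uses
the add-one rule, `p = (1 + #{F_sim >= F_obs})/(n_sim + 1)`, hence is never
exactly 0. Because observed and simulated traits are exchangeable under
the null, the test is exact up to permutation discreteness; the suite
measures a 5.6% rejection rate at nominal 5% over 500 Brownian-null
replicates with clade-confounded groups (binomial SD ≈ 1%).

Post-hoc pairwise comparisons use t statistics with the pooled ANOVA MSE,
referred to the same simulations (two-sided, on |t|), Bonferroni-corrected
by the number of pairs actually performed.

## Independent contrasts

Felsenstein's pruning algorithm, with polytomies first resolved to
zero-length branches in a deterministic (alphabetical) order. Contrasts of
a trait on an n-tip tree number exactly n-1; the sum of squared contrasts
equals the GLS quadratic form `(x-μ̂)'C⁻¹(x-μ̂)` under the BM covariance
`C` (verified as an oracle identity in the tests). The contrast
correlation is computed through the origin, with a two-sided t reference
on n-2 degrees of freedom; a pair of sister branches both of length zero
makes the contrast undefined and raises.

## Rank-based lineage tests

Lineage membership is phylogenetically structured by definition, so for
lineage comparisons plain rank statistics are used and interpreted
descriptively: Kruskal–Wallis with midranks and tie correction, followed by
pairwise two-sided Wilcoxon rank-sum tests with Bonferroni correction only
when the global test is significant at α = 0.05.

## DAPC

Data are centered but not scaled by default — disparity values already
live on a common [1/k, 1] scale; scaling is available and makes
contributions invariant to per-character affine rescaling. PCA is an SVD
of the centered matrix; LDA runs on the retained scores; the number of
discriminant axes is min(groups-1, PCs retained). Per-character
contributions back-map the LDA scalings through the PCA rotation
(`v_a = R w_a`), square them, weight axes by their between-group
eigenvalue share, and normalize to sum to 1.

Cross-validation holds out 10% per group (stratified), refits on the rest,
and scores each retention level by the RMSE of (1 - assignment success)
over replicates; ties in the argmin break toward fewer PCs. Retention
levels above the training-data rank are skipped with a warning. The
default retention grid has at most 20 levels. The cluster search runs
k-means on the full PCA scores and reports
`BIC(k) = n·log(WSS/n) + k·log(n)` without choosing automatically: beyond
the true number of groups the curve is nearly flat (the per-split WSS gain
fights the log-n penalty), so the curve is meant to be read for an elbow,
and a monotone curve means no defensible grouping.

## Ages, calibration and WGD arithmetic

Stem age = age of the parent of the tribe's subtending branch; crown age =
age of the tribe's MRCA (undefined for single-genus tribes); lag-phase =
stem - crown, nonnegative for tree-derived pairs by construction. Groups
of tribes unresolved beyond a polytomy can be merged into one age group
via configuration, all members then sharing the pooled stem and crown age.

The calibration regression takes the external study's crown age as
predictor and the focal tree's as response (the imputation fills values on
the tree's scale), reporting Spearman's ρ alongside the OLS fit; at least
three shared tribes are required. Imputation only fills tribes without a
tree-derived crown age, and predictions above the stem age are clipped to
it with a warning. The sample (n-1) SD convention is used in every
summary, and genome-size variation is SD/mean restricted to tribes with at
least three estimates.

WGD rate = mean WGDs per genus / elapsed my × 10; with the published
inputs (1.45 WGDs per genus over 35 my; 4 WGDs over 440 my) this gives
0.41 and 0.09 WGD/10 my.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with defaults matching the study system: 51 tribes in 3 lineages, ~350
genera (zero-truncated geometric, mean 6.9 genera/tribe), 37 characters
with 111 states (12 binary, 15 three-state, 8 four-state, 2 five-state),
root age 32 my, 11 WGD-flagged and 9 rate-shift-flagged tribes restricted
to the two larger lineages, and no missing cells by default (the empirical
matrix is fully scored). Flag counts scale proportionally when `n_tribes`
is changed.

**Tree.** A birth–death backbone over tribes (λ = 0.3, μ = 0.1 per my)
conditioned on the tribe count, with terminal branches extended by the
exponential waiting time to the next event (the simulator otherwise stops
exactly at the last speciation, leaving a zero-age node) and rescaled to
the root age. Conditioned birth–death trees rescaled this way concentrate
node ages near the present (mean tribal stem age ~5 my), whereas the
empirical chronogram has stem ages of ~15 ± 5 my and crown ages of
~10 ± 5 my; a monotone power transform on backbone node ages
(`node_age_power = 0.3`, i.e. `age → root·(age/root)^0.3`) deepens the
backbone to that scale while preserving parent–child ordering. Within-tribe
crown ages are drawn uniformly at 0.4–0.9 of the stem age (centering the
crown/stem ratio on the empirical ~0.66, mean lag-phase ≈ 5 my), with
random ultrametric subtrees below. Resulting synthetic summaries: stem
15.3 ± 5.6 my, crown 10.0 ± 4.5 my, mean lag 5.3 my. Tribes and lineages
are monophyletic by construction.

**Characters.** Symmetric Mk (all transitions equally likely — the
characters are unordered and no asymmetry is assumed), simulated with the
exact k-state transition probability per branch
(`p_stay = 1/k + (k-1)/k · e^{-qtk/(k-1)}`), baseline rate
q = 0.03 /my — chosen once so that realized tribal disparity is
mid-to-upper range rather than saturated or frozen; under the calibrated
tree depths this yields a mean tribal direct disparity of ≈ 0.8. Genus
polymorphism arises by simulating 3 pseudo-species along each terminal
branch and taking the union of their states. Branches inside WGD-flagged
tribes (stem branch and below) evolve at `q × m`; `m` defaults to 1 (no
planted effect) and power experiments raise it explicitly — at m = 4 and
the default shape, the phylogenetic ANOVA on mean disparity detects the
elevation in ≳80% of replicates. Lineage-private states are reserved out
of the Mk state space and planted at an exact tribal prevalence, so
lineage-frequency recovery can be asserted exactly. Missing cells are
masked independently at a configurable fraction.

**What the generator does not emulate**: correlated evolution among
characters, asymmetric or ordered state transitions, diversification-rate
heterogeneity beyond the planted flags, within-genus sampling biases, and
the ecological covariates' real causal structure (richness and rates are
drawn from simple parametric stand-ins). Passing tests therefore
demonstrate correctness and calibration of the statistics under the
stated generative model, not robustness to these empirical complications.

## Problem sizes and runtime

The acceptance script and test suite use: 1000 random matrices for the
disparity invariants; 100 small trees (4–6 tips) for the Moran brute-force
check; 500 Brownian-null replicates with `n_sim = 200` for the ANOVA
type-I calibration; 200 replicate trait pairs for the PIC correlation
type-I; 200 full-shape replicates (51 tribes, 37 characters,
`n_sim = 100`) for the planted-WGD power; 10⁴ draws for the Mk
stationarity χ². These sizes put all Monte-Carlo standard errors well
inside the asserted tolerances while keeping a full run to a few minutes
on one CPU.

## Known limitations

- The tribal-age deepening is a phenomenological transform, not a
  mechanistic diversification model; synthetic lineages-through-time
  curves should not be interpreted biologically.
- The BIC cluster search inherits the near-flat tail of its criterion;
  it reports the curve and deliberately never auto-selects k.
- Imputed crown ages are regression point estimates without uncertainty;
  downstream lag-phases using them carry no error bars.
- `pic` requires strictly positive denominator branch sums; trees with
  sister tips at identical positions (both branch lengths 0) are rejected
  rather than jittered.
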