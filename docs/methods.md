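# Methods

This note records the models behind `coraldepth`, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
establish about real data.

## Data model

A `TimeTree` stores a rooted phylogeny in flat arrays indexed by post-order
node ids (children before parents, root last), so posterior samples, branch
categories and reconstructions indexed by node id stay aligned across every
operation without label bookkeeping. Each non-root node owns the branch
above it; branches carry a length in Ma and a dimensionless rate scalar
*r* (default 1). Any root edge in the input is ignored, which is what makes
a binary *n*-tip tree yield exactly 2n − 2 ancestor–descendant (PAD)
comparisons and 2n − 1 nodes. Node ages are defined as root age minus
root-to-node path length, so non-ultrametric trees are accepted rather than
rejected. Scalars serialize as `[&r=...]` Newick comment tags, which plain
readers skip.

## Occurrence curation

Three record-level filters, applied in a fixed order (bathymetry, photic
gap, depth cap), each with its threshold exposed as an argument:

* **bathymetry consistency** (tolerance 500 m) — wide because gridded
  bathymetry is coarse relative to point records;
* **photic-gap rule** for zooxanthellate species (cutoff 165 m, gap 50 m) —
  "consecutive occurrences" is read as consecutive in sorted depth order
  per species; the chain starts from the deepest record at or above the
  cutoff (records exactly at the boundary count as above it) and everything
  beyond the first gap > 50 m is dropped. If a species has no record above
  the cutoff, the first deep record is measured against the cutoff itself.
* **azooxanthellate cap** at 5740 m.

Range summaries use the median occurrence depth (robust to the sharp decay
of sampling effort with depth), clamp depths below 1 m to 1 m before log₁₀,
take the maximum of absolute latitudes, and set the minimum latitude to zero
for ranges crossing the equator. Agreement between two curations of the
same data is measured by Spearman's ρ per depth metric, since only the
ranking of species needs to be preserved for downstream rank-based tests.

## Continuous evolution

**Likelihood.** Brownian motion on the (rate-scaled) tree, computed by
post-order Gaussian message passing in O(n). Pagel's λ is implemented as a
branch-length transform — internal branches × λ, each pendant branch
extended by (1 − λ) times its tip's scaled depth — which multiplies shared
covariance by λ while preserving tip variances, for ultrametric and
non-ultrametric trees alike. The pruning path is checked against an
independent dense multivariate-normal oracle in the tests.

**Regression.** For fixed covariance the coefficients and the rate are
conjugate (flat prior on β, Jeffreys on σ²), so PGLS samples them exactly
and only λ needs a reflected random-walk Metropolis step against the
analytically marginalized likelihood. An optional `shrinkage_sd` switches
the flat β prior to N(0, (shrinkage·σ)²) per coefficient; it is off by
default (so point estimates coincide with GLS/OLS) and turned on only where
designs can become collinear by construction — a trait group with two tips,
or path-wise-rate predictors on a tree with no significant scalars, where
all tips share one path-wise rate. The reported R² is computed in the GLS
metric against an intercept-only fit.

**Variable rates.** The rate-heterogeneity model multiplies branch lengths
by scalars placed on single branches or whole clades (a clade scalar covers
the stem and everything below it; overlapping placements multiply). Because
β and σ² are marginalized analytically, the reversible-jump chain moves
only in scalar space: birth (a free branch or clade, value drawn from the
prior), death, and a log-scale random-walk update. Priors: the number of
placed scalars is geometric (p = 0.5), values are log-uniform on
[1/100, 100]. With the value prior doubling as the birth proposal the
acceptance ratios reduce to likelihood ratios times small combinatorial
terms. Conjugate (β, σ²) draws and the conditional Brownian log likelihood
are recorded per retained sample, so the all-scalars-at-1 state reproduces
the plain BM likelihood exactly.

The **median scaled tree** keeps a branch's posterior-median scalar only if
the branch is scaled in more than half the posterior sample and the median
magnitude exceeds 2. The original formulation of this rule states only the
"larger than two" side; for compressions the symmetric rule (median < ½) is
applied here, and both thresholds are arguments. Branches then classify as accelerated (r > 1),
constant, or decelerated.

**Partitioned rates** fix the scalar structure a priori (one scalar per
lineage category) and sample the category log-rates by random-scan
Metropolis under the same marginalization. With σ² integrated out only rate
*ratios* are strongly identified — which matches the downstream use, where
each tree's category rates are divided by the tree's minimum before
cross-tree comparison.

**Model comparison.** Stepping-stone sampling with a Beta(0.4, 1)-quantile
temperature ladder (stones concentrated near the prior); the β = 0 stone
samples the prior directly, later stones run short Metropolis chains on the
power posterior. The defaults (32 stones × 400 iterations) are deliberately
far below production settings (analyses of this kind typically run ~1000
stones × 10⁴ iterations); on the conjugate normal toy they land within a few
hundredths of a nat of the closed form. The log Bayes factor is
2 × (log ML complex − log ML simple), with > 2 read as positive and > 10 as
very strong evidence. Some published descriptions of this comparison print
the subtraction in the opposite order while interpreting BF > 2 as support
for the complex model; this implementation keeps both marginal likelihoods
in the report so the orientation is never ambiguous. Posterior significance of a coefficient or
contrast is min(P(x < 0), P(x > 0)) < 0.05.

## Discrete evolution

Symbiosis and coloniality evolve jointly as a 4-state chain over
{AS, AC, ZS, ZC} with the two dual-transition rates fixed at zero (8 free
rates) — the dependent-model structure that makes trait correlation
estimable. Transition probabilities come from one eigendecomposition per
likelihood evaluation, vectorized over branch lengths, with a scipy `expm`
fallback. The root state distribution defaults to the stationary
distribution of Q (uniform and explicit vectors are accepted); analyses in
this model family rarely state their choice, so it is left configurable. Facultative species enter as
ambiguity vectors over their two compatible states.

Rates get exponential priors whose mean carries a uniform(0, 10)
hyperprior; the sampler is a single-rate log-scale random walk plus a
reflected walk on the hypermean, with optional reversible-jump zeroing of
individual rates. Node marginals are exact per rate draw (up–down pruning)
and summarized by the across-draw median, then renormalized — medians of
probabilities do not sum to one, and renormalizing after the median keeps
the per-state robustness while restoring a distribution.

A covarion-style extension (hidden on/off rate class, 8 visible×hidden
states) is available behind a flag; the plain dependent model is the
default, as the analyses this supports specify no switching parameters.

## Lineage categories

Per trait, a node call is made when the trait's marginal posterior reaches
a support threshold (default 0.7, configurable; it is a knob, not a claim
about the right cutoff). A branch's per-trait status is the shared
state, a transition (both ends assigned, different), or uncertain (either
end uncalled). The sixteen raw combinations merge to eight categories;
transition–transition, uncertain–solitary and uncertain–transition are
excluded from analysis (they essentially never occur), and the merge
arithmetic is pinned by tests to the published category counts
(TransS 23, TransC 16, UncS 7, UncC 77).

## Ancestral depth ranges

Median and maximum log-depth are reconstructed in two separate fits of
depth against the *path-wise rate* (root-to-node distance on the
rate-scaled tree) with group intercepts and slopes — AS, AC, and a merged
ZS-ZC group, real tips hard-coded (0.5/0.5 for facultatives) and internal
nodes soft-coded by their state posteriors. Predictions are made at
zero-length false tips grafted onto each internal node; operationally this
is the conditional multivariate-normal mean given the tip data, which is
exactly what a false tip with zero branch length receives, so no singular
covariance is ever formed. Reported uncertainty combines the spread of the
posterior predictive mean with the conditional variance.

Nodes where the median fit exceeds the maximum fit are reconciled by
swapping (flagged per node); reconstructions below 1 m are clamped to the
1 m floor used throughout. The minimum is then back-calculated as
2·median − max on the metre scale (the limits are symmetric about the
median there, not on the log scale), clamped at 1 m. The tension of
back-calculating a symmetric minimum from an occurrence-based median is
inherent to the procedure and documented rather than resolved.

## Trend statistics

PAD deltas (descendant − ancestor log-depth, per branch) telescope along
paths by construction. Direction tests are exact two-sided binomials
against 0.5; exact-zero deltas are excluded from the trials but counted,
since the source is silent and near-zero average changes do occur.
Cross-tree rate comparisons standardize each tree by its minimum category
rate, log-transform, report Shapiro–Wilk descriptively, and test with
Kruskal–Wallis plus pairwise two-sided Wilcoxon rank-sum tests under Holm
correction at 0.05. Long-term trends regress node depth on node age (Ma
before present; a negative age coefficient means shallower at older ages)
with per-category terms, separately for the joined slow stratum (constant +
decelerated, joined because decelerations are rare) and the accelerated
stratum, excluding categories with fewer than ten members. The
depth-vs-scalar and depth-vs-path-wise-rate associations are Bayesian
regressions with category covariates; groups with too few tips are pooled
into a shared intercept rather than silently absorbing a slope.

## Synthetic data

The generators define the study conditions for every test:

* **Trees**: birth–death conditioned on the tip count (grow to n extant
  lineages, extend pendant branches into the next inter-event interval,
  prune extinct lineages), defaults 0.06/0.02 events per Ma — a net
  diversification producing root ages of a few hundred Ma at ~500 tips,
  the scale of the empirical system. Conditioning this way avoids the
  zero-length sister tips that stopping exactly at the n-th speciation
  produces (they make Brownian covariances singular).
* **Traits**: exact Gillespie simulation of the 4-state chain per branch.
* **Depth**: Brownian increments with variance σ²·length·r, default
  σ² = 0.005 log₁₀-units² per Ma from a root at log₁₀ depth 3 (1000 m,
  a bathyal origin); trends, when requested, are deterministic per-branch
  drifts β·length on labelled branches — real trends are emergent, but
  tests need a controllable signal.
* **Occurrences**: uniform within each species' depth/latitude box, placed
  in bathymetry cells matching their depth (the synthetic raster is a
  regular one-degree grid whose cell depth increases eastward 25–5925 m,
  nearest-cell lookup); planted violations each break exactly one rule, so
  curation recall and false-drop rates are exact by construction.

What passing these tests shows: the estimators recover what they claim
under the model they assume, at realistic sizes, with controlled error
rates. What they do not show: robustness to model violations real data
carry — spatially structured sampling, taxonomic error, non-Brownian depth
evolution, trait-dependent diversification, or phylogenetic error. The
empirical headline numbers of the motivating system (a 510-species tree
and half a million records) are deliberately out of scope.

## Problem sizes and calibration suites

The calibration tests run at sizes chosen for statistical power rather than
fidelity to the empirical data: λ-recovery uses 20 datasets of 200 tips
(fresh tree per dataset); clade detection 20 replicates of 80-tip trees
with a 25× clade; partition-ratio recovery 10 replicates of 100-tip trees
with a ~35-tip fast clade — sized so the variance-ratio estimator's
sampling noise (≈ exp(±1.64·√(2/df)) around the true ratio) stays inside
the [5, 20] acceptance window; type-I suites use 20 null variable-rates
runs and 100 Kruskal–Wallis null tables. Chains are scaled down
throughout (thousands, not millions, of iterations); the conjugate
marginalization makes short chains informative because only λ or the
scalar configuration mixes by MCMC.

## Interfaces

The package is a library: the importable API plus `examples/` scripts are
the interface, and `scripts/acceptance.py` is the one batch entry point.
Chain outputs, range tables, branch categories and node estimates are plain
pandas DataFrames/arrays; trees and grids read and write plain-text formats
(Newick/NEXUS, an ASCII grid).

## Known limitations

* The VR sampler rebuilds the dense tip covariance per proposal (O(n²));
  fine to a few hundred tips, not thousands.
* Stepping-stone assumes the model adapter's prior is proper and samplable;
  the improper-prior marginals used inside the VR/PGLS machinery are for
  ratios only and never mix with stepping-stone output.
* The covarion extension is structural (hidden on/off classes) and lightly
  exercised; the default analyses never enable it.
* Medians-then-renormalize for node state posteriors is faithful to the
  source's wording but is not the posterior mean; with multimodal
  posteriors the two can differ.
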