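# coraldepth

Phylogenetic inference of depth colonization in scleractinian corals — and,
more generally, of how a continuous niche axis (log₁₀ depth) evolved along a
time-calibrated phylogeny under branch-specific rates, and how two correlated
binary innovations (photosymbiosis and coloniality) shaped that history.

The package is aimed at macroevolutionary biologists who want to run the full
inference chain on their own trees and occurrence data, or to study its
statistical behaviour on synthetic data where the truth is known.

## What it computes

Given a rooted time tree (branch lengths in Ma), species occurrence records
(longitude, latitude, depth) and per-species trait flags, the pipeline:

1. **Curates occurrences** — drops records whose depth disagrees with a
   gridded bathymetry by more than 500 m, isolated records of zooxanthellate
   species below the 165 m photic register unless consecutive sorted depths
   are ≤ 50 m apart, and azooxanthellate records beyond 5740 m; then
   summarizes per-species min/median/max depth (median, not mean, because
   sampling effort decays with depth) and latitude.
2. **Fits variable-rates Brownian motion** — log₁₀ depth evolves as BM with
   rate σ² while a reversible-jump MCMC places multiplicative scalars *r* on
   branches or clades: *r* = 1 is the single-rate background, *r* > 1 a
   stretched branch (accelerated colonization), 0 < *r* < 1 a compressed one.
   The *median scaled tree* keeps a branch's posterior-median scalar only if
   it is scaled in > 50 % of the posterior with median magnitude beyond 2
   (symmetrically below ½). Pagel's λ, phylogenetic regression (PGLS /
   phylogenetic ANOVA with dummy coding, facultative species coded 0.5/0.5),
   stepping-stone marginal likelihoods and log Bayes factors
   (log BF = 2 Δlog ML; > 2 positive, > 10 very strong) round out the model
   kit.
3. **Reconstructs trait history** — the two binary traits evolve as a 4-state
   Markov chain over {AS, AC, ZS, ZC} with dual transitions disallowed
   (8 free rates, exponential priors with a uniform(0, 10) hypermean);
   per-node marginal posteriors come from an exact up–down pruning pass,
   summarized by the across-sample median and renormalized.
4. **Classifies lineages** — each branch gets one of eight categories
   (AS, AC, ZS, ZC, TransS, TransC, UncS, UncC) by merging the sixteen raw
   per-trait statuses of its two ends; transition–transition,
   uncertain–solitary and uncertain–transition branches are excluded.
5. **Reconstructs ancestral depth ranges** — median and maximum log-depth at
   every internal node by predictive modelling at zero-length "false tips"
   on the rate-scaled tree, with node state posteriors as soft group codes
   (ZS and ZC merged); the minimum is back-calculated as
   log₁₀[2·median − max] on the metre scale, clamped at 1 m.
6. **Tests trends** — phylogenetic ancestor–descendant (PAD) comparisons
   (one Δ log₁₀ depth per branch) with exact binomial direction tests;
   per-category colonization rates standardized within each tree by its
   minimum, compared across a tree sample by Kruskal–Wallis plus
   Holm-adjusted pairwise Wilcoxon tests; long-term depth-vs-age regressions
   per rate stratum; and depth-vs-scalar / depth-vs-path-wise-rate
   associations.

A full synthetic-data module (`coraldepth.synthetic_data`) generates every
input — birth–death trees, correlated trait histories, rate-heterogeneous
depths, occurrence tables with planted curation violations — so each stage is
testable without downloads.

## Worked example

`examples/02_variable_rates.py` simulates an 80-tip tree on which one
10-tip clade colonizes depth 25× faster, then asks the variable-rates model
to find it:

```
tree: 80 tips, clade of 10 tips simulated at r = 25
chain: 380 retained samples, acceptance 0.44
branches flagged inside the fast clade:  12 / 19
branches flagged outside the fast clade: 0 / 139
median scalar across clade branches: 21.0
```

The chain recovers the acceleration (median scalar 21 against a true 25)
with no false positives among the 139 background branches. The other
examples walk through occurrence curation (`01`), ancestral trait and depth
reconstruction (`03` — e.g. a root simulated at 1000 m is reconstructed
with median 874 m and interval 1–1863 m), and PAD/trend statistics (`04`).

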