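"""Ancestor-descendant direction tests and cross-tree rate comparisons.

Computes one phylogenetic ancestor-descendant (PAD) comparison per branch of
a simulated depth history with a built-in shallowing trend, tests the
shallower/deeper split with exact binomial tests, and compares lineage-
category colonization rates across a sample of trees with Kruskal-Wallis
and Holm-adjusted pairwise Wilcoxon tests.
"""

import numpy as np
import pandas as pd

import coraldepth as cd

tree = cd.simulate_tree(n_tips=120, birth=0.08, death=0.02, seed=21)
rng = np.random.default_rng(3)
categories = rng.choice(["AS", "AC", "ZC"], size=tree.n_nodes - 1,
                        p=[0.4, 0.2, 0.4])

# depth drifts shallower (negative log-depth trend) on AS branches only
depth_log = cd.simulate_depth(
    tree, sigma2=0.004, root_depth_log=3.0, seed=4,
    trend_beta_by_group={"AS": -0.004},
    branch_groups={int(i): categories[i] for i in range(tree.n_nodes - 1)})

pads = cd.compute_pad_deltas(tree, {"med": depth_log}, categories=categories)
tests = cd.direction_tests_by_category(pads, limits=("med",))
print("PAD direction tests (prop. shallower vs 0.5, exact binomial):")
print(tests[["category", "n", "prop_shallower", "p_value"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

# cross-tree partitioned-rate comparison: category "c" is 10x faster
rates = pd.DataFrame(np.exp(rng.normal(0, 0.3, size=(50, 5))),
                     columns=["AS", "AC", "ZC", "TransS", "UncC"])
rates["AC"] *= 10.0
cmp_ = cd.compare_partition_rates(rates)
print(f"\nKruskal-Wallis over standardized log rates: "
      f"H = {cmp_.kruskal.statistic:.1f}, p = {cmp_.kruskal.p_value:.2g}")
sig = cmp_.pairwise[cmp_.pairwise["significant"]]
print(f"significant Holm-adjusted pairwise contrasts: {len(sig)} "
      f"(all involving AC: {bool(((sig['a']=='AC')|(sig['b']=='AC')).all())})")
print("\nWithin each tree, rates are divided by the tree's minimum "
      "(slowest category = 1) and log10-transformed before testing.")
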