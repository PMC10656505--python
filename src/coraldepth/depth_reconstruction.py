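"""Ancestral depth ranges by phylogenetic predictive modelling.

Median and maximum log10 depth at every internal node are reconstructed by
regressing tip depths on the *path-wise rate* — the root-to-node distance on
the rate-scaled tree — with group-specific intercepts and slopes, and then
predicting at "false tips": zero-length pseudo-tips grafted onto each
internal node.  A false tip shares its host node's path-wise rate and
phylogenetic covariance with the data, so its conditional prediction under
the fitted Gaussian model is the node estimate, informed simultaneously by
the regression mean and by the observed values of nearby tips.

Real tips enter the design with hard 0/1 group codes (0.5/0.5 for
facultative species); false tips use the node's posterior state
probabilities as soft codes.  Because zooxanthellate solitary and colonial
corals behave alike in this step they are merged into one ZS-ZC group by
default (their probabilities summed).

The minimum depth is not reconstructed directly — species piling up at the
surface leave too many repeated shallow values — but back-calculated from
the reconstructed median and maximum on the metre scale, where the two
limits sit symmetrically about the median: min = 2*median - max, clamped to
1 m before relogging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .treekit import TimeTree
from .continuous_evolution import (
    GROUPS, build_design_matrix, tip_covariance, _align_tip_values,
    _gls_stats, _mvn_draw,
)

DEFAULT_MERGE = {"AS": "AS", "AC": "AC", "ZS": "ZS-ZC", "ZC": "ZS-ZC"}


def _merged_columns(merge_map: dict[str, str]) -> list[str]:
    out = []
    for g in GROUPS:
        m = merge_map[g]
        if m not in out:
            out.append(m)
    return out


def _merge_codes(codes4: np.ndarray, merge_map: dict[str, str]) -> np.ndarray:
    cols = _merged_columns(merge_map)
    X = np.zeros((codes4.shape[0], len(cols)))
    for j, g in enumerate(GROUPS):
        X[:, cols.index(merge_map[g])] += codes4[:, j]
    return X


def _node_tip_shared_depth(tree: TimeTree) -> np.ndarray:
    """Scaled root-to-MRCA depth for every (node, tip) pair."""
    d = tree.depths_from_root(use_scalars=True)
    tb = tree.tips_below()
    M = np.zeros((tree.n_nodes, tree.n_tips))
    clade_cache: dict[int, np.ndarray] = {}

    def clade(i):
        if i not in clade_cache:
            clade_cache[i] = tree.clade_nodes(i)
        return clade_cache[i]

    for i in range(tree.n_nodes):
        M[i, tb[i]] = d[i]  # node is the MRCA of itself and tips below it
        if tree.is_tip[i]:
            continue
        ch = tree.children[i]
        for a in range(len(ch)):
            for b in range(len(ch)):
                if a == b:
                    continue
                M[np.ix_(clade(ch[a]), tb[ch[b]])] = d[i]
    return M


def _predict_nodes(tree, y, X_tips, X_nodes, node_ids, n_samples, seed,
                   shrinkage_sd: float = 30.0):
    """Posterior predictive mean/sd at internal nodes via conditional MVN.

    Coefficients carry a very diffuse conjugate shrinkage prior (sd 30
    residual units per coefficient) purely to keep nearly-unidentified
    directions — a trait group represented by a couple of tips — from
    producing astronomical predictive draws.
    """
    V = tip_covariance(tree, use_scalars=True)
    L = np.linalg.cholesky(V)
    M = _node_tip_shared_depth(tree)
    C = M[node_ids]                         # cov(node value, tip values)
    d = tree.depths_from_root(use_scalars=True)[node_ids]
    CVi = np.linalg.solve(L.T, np.linalg.solve(L, C.T)).T
    cond_var = np.maximum(d - np.sum(CVi * C, axis=1), 0.0)

    rng = np.random.default_rng(seed)
    ridge = 1.0 / shrinkage_sd ** 2
    beta_hat, XtViX, S, _ = _gls_stats(V, X_tips, y, ridge)
    nu = len(y) - X_tips.shape[1]
    XtViX_inv = np.linalg.inv(XtViX)
    preds = np.empty((n_samples, len(node_ids)))
    sig = np.empty(n_samples)
    betas = np.empty((n_samples, X_tips.shape[1]))
    for s in range(n_samples):
        s2 = S / rng.chisquare(nu)
        beta = _mvn_draw(beta_hat, s2 * XtViX_inv, rng)
        resid = y - X_tips @ beta
        preds[s] = X_nodes @ beta + CVi @ resid
        sig[s] = s2
        betas[s] = beta
    mean_pred = np.median(preds, axis=0)
    sd_pred = np.sqrt(np.var(preds, axis=0) + np.mean(sig) * cond_var)
    return mean_pred, sd_pred, betas


def back_calculate_min_depth(median_log, max_log):
    """Minimum log10 depth from reconstructed median and maximum.

    Unlogs both limits, takes ``min = 2*median - max`` (the limits are
    symmetric about the median on the metre scale), clamps to >= 1 m, and
    relogs.  Accepts scalars or arrays; raises if any median exceeds its
    maximum.
    """
    med = np.asarray(median_log, dtype=float)
    mx = np.asarray(max_log, dtype=float)
    if np.any(med > mx + 1e-12):
        raise ValueError("median depth exceeds maximum depth")
    mn = 2.0 * 10.0 ** med - 10.0 ** mx
    mn = np.maximum(mn, 1.0)
    out = np.log10(mn)
    return float(out) if out.ndim == 0 else out


def reconstruct_node_depths(
    tree: TimeTree,
    tip_median_log,
    tip_max_log,
    node_state_probs: np.ndarray,
    tip_groups,
    tip_facultative=None,
    merge_map: dict[str, str] | None = None,
    n_samples: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruct median and maximum log10 depth at every internal node.

    ``tree`` should already carry the significant branch scalars (the median
    scaled tree), so path-wise rates and the covariance reflect variable
    rates.  ``node_state_probs`` is the (n_nodes, 4) posterior over combined
    trait states; ``tip_groups``/``tip_facultative`` give the hard codes for
    real tips.  Median and maximum are fitted in two separate regressions
    and combined per node; nodes where the reconstructed median exceeds the
    maximum are reconciled by swapping (flagged in ``reconciled``).  The
    minimum is then back-calculated.
    """
    merge_map = merge_map or dict(DEFAULT_MERGE)
    if node_state_probs.shape != (tree.n_nodes, 4):
        raise ValueError("node_state_probs must be (n_nodes, 4); missing posteriors?")
    y_med = _align_tip_values(tree, tip_median_log)
    y_max = _align_tip_values(tree, tip_max_log)

    pw = tree.depths_from_root(use_scalars=True)
    codes_tips = _merge_codes(build_design_matrix(tip_groups, tip_facultative), merge_map)
    pw_tips = pw[tree.tip_ids]

    node_ids = np.flatnonzero(~tree.is_tip)
    codes_nodes = _merge_codes(np.asarray(node_state_probs, dtype=float)[node_ids],
                               merge_map)
    # a merged group with no tips cannot be fitted: drop its columns
    present = codes_tips.sum(axis=0) > 0
    X_tips = np.hstack([codes_tips[:, present],
                        codes_tips[:, present] * pw_tips[:, None]])
    X_nodes = np.hstack([codes_nodes[:, present],
                         codes_nodes[:, present] * pw[node_ids][:, None]])

    med, med_sd, med_betas = _predict_nodes(tree, y_med, X_tips, X_nodes,
                                            node_ids, n_samples, seed)
    mx, mx_sd, mx_betas = _predict_nodes(tree, y_max, X_tips, X_nodes,
                                         node_ids, n_samples, seed + 1)
    reconciled = med > mx
    med2 = np.where(reconciled, mx, med)
    mx2 = np.where(reconciled, med, mx)
    # like the species summaries, depths shallower than 1 m are clamped to
    # 1 m (log10 = 0) so the reconstructed range stays on the metre scale
    med2 = np.maximum(med2, 0.0)
    mx2 = np.maximum(mx2, 0.0)
    mn = back_calculate_min_depth(med2, mx2)

    cols = _merged_columns(merge_map)
    out = pd.DataFrame({
        "node_id": node_ids,
        "log_depth_median": med2,
        "log_depth_max": mx2,
        "log_depth_min": mn,
        "sd_median": med_sd,
        "sd_max": mx_sd,
        "pathwise_rate": pw[node_ids],
        "reconciled": reconciled,
    })
    for j, c in enumerate(cols):
        out[f"p_{c}"] = codes_nodes[:, j]
    kept = [c for c, p in zip(cols, present) if p]
    names = [f"intercept_{c}" for c in kept] + [f"slope_pw_{c}" for c in kept]
    out.attrs["coef_names"] = names
    out.attrs["beta_samples_median"] = med_betas
    out.attrs["beta_samples_max"] = mx_betas
    return out


def phylomorphospace_table(
    tree: TimeTree,
    node_estimates: pd.DataFrame,
    tip_ranges: pd.DataFrame,
    branch_categories: pd.DataFrame | None = None,
    rate_classes: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per node and tip (2n - 1 rows for a binary n-tip tree).

    Tips carry their observed log-depth range (from ``tip_ranges``, indexed
    by species); internal nodes their reconstructed range.  Each row also
    reports the lineage category and rate class of the branch above the
    node (the root gets ``"root"``).
    """
    ages = tree.node_ages()
    est = node_estimates.set_index("node_id")
    tr = tip_ranges.set_index("species") if "species" in tip_ranges.columns else tip_ranges
    cat = None
    if branch_categories is not None:
        cat = branch_categories.set_index("branch_id")["category"]
    rows = []
    for i in range(tree.n_nodes):
        row = {"node_id": i, "label": tree.labels[i],
               "is_tip": bool(tree.is_tip[i]), "age_ma": ages[i]}
        if tree.is_tip[i]:
            sp = tr.loc[tree.labels[i]]
            row.update(log_depth_min=sp["log_depth_min"],
                       log_depth_median=sp["log_depth_median"],
                       log_depth_max=sp["log_depth_max"])
        else:
            e = est.loc[i]
            row.update(log_depth_min=e["log_depth_min"],
                       log_depth_median=e["log_depth_median"],
                       log_depth_max=e["log_depth_max"])
        row["category"] = ("root" if i == tree.root
                           else (cat.loc[i] if cat is not None else None))
        row["rate_class"] = (None if rate_classes is None or i == tree.root
                             else rate_classes[i])
        for c in ("log_depth_min", "log_depth_median", "log_depth_max"):
            row[c.replace("log_depth", "depth") + "_m"] = 10.0 ** row[c]
        rows.append(row)
    return pd.DataFrame(rows)
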