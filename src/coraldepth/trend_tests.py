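"""Directional statistics on the reconstructed depth history.

Four families of tests summarize how coral lineages moved along the depth
gradient:

* **PAD comparisons** — one phylogenetic ancestor-descendant contrast per
  branch (delta log10 depth, descendant minus ancestor, for the minimum and
  maximum range limits), with exact two-sided binomial tests of the
  shallower/deeper split against 0.5;
* **partitioned-rate comparison** — per-tree posterior median rates for the
  eight lineage categories, standardized within each tree by its minimum
  rate, log-transformed, and compared by Kruskal-Wallis plus pairwise
  Wilcoxon rank-sum tests with Holm correction;
* **long-term trend regressions** — node depth against node age, with
  category covariates, fitted separately for lineages that evolved at slow
  (constant or decelerated, joined) versus accelerated rates;
* **depth-rate associations** — maximum depth against the branch scalar,
  and current depth against the path-wise rate per group (PGLS with
  lambda estimated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .treekit import TimeTree
from .continuous_evolution import (
    RegressionFit, bayesian_lm, build_design_matrix, pgls_regression,
    RATE_ACCELERATED, RATE_CONSTANT, RATE_DECELERATED,
)

SHALLOWER = "shallower"
DEEPER = "deeper"
UNCHANGED = "none"


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PAD deltas and binomial direction tests


def compute_pad_deltas(
    tree: TimeTree,
    node_values: dict[str, np.ndarray],
    categories=None,
) -> pd.DataFrame:
    """Per-branch descendant-minus-ancestor depth changes.

    ``node_values`` maps a limit name (e.g. ``"min"``, ``"max"``) to an
    array of log10 depths over *all* node ids (tips and internal nodes).
    A negative delta means the descendant sits shallower than its ancestor.
    Deltas telescope: summed along any root-to-tip path they equal the tip
    value minus the root value.
    """
    for name, v in node_values.items():
        v = np.asarray(v, dtype=float)
        if v.shape != (tree.n_nodes,) or not np.all(np.isfinite(v)):
            raise ValueError(f"node values {name!r} must be finite, one per node")
    rows = []
    for pad in tree.enumerate_pads():
        row = {"branch_id": pad.branch_id, "ancestor": pad.ancestor,
               "descendant": pad.descendant}
        if categories is not None:
            row["category"] = categories[pad.branch_id]
        for name, v in node_values.items():
            delta = float(v[pad.descendant] - v[pad.ancestor])
            row[f"delta_{name}"] = delta
            row[f"direction_{name}"] = (
                SHALLOWER if delta < 0 else DEEPER if delta > 0 else UNCHANGED
            )
        rows.append(row)
    return pd.DataFrame(rows)


def binomial_direction_test(deltas) -> TestResult:
    """Exact two-sided binomial test of shallower vs deeper against 0.5.

    Zero deltas are excluded from the trials but counted in ``extra``.
    With no nonzero deltas the result carries n = 0 and an undefined-p flag
    (p_value = NaN).
    """
    d = np.asarray(deltas, dtype=float)
    n_sh = int(np.sum(d < 0))
    n_dp = int(np.sum(d > 0))
    n_zero = int(np.sum(d == 0))
    n = n_sh + n_dp
    if n == 0:
        return TestResult(np.nan, np.nan, 0,
                          extra={"n_zero": n_zero, "undefined": True})
    res = stats.binomtest(n_sh, n, 0.5, alternative="two-sided")
    return TestResult(
        statistic=n_sh / n, p_value=float(res.pvalue), n=n,
        extra={"n_shallower": n_sh, "n_deeper": n_dp, "n_zero": n_zero,
               "percent_shallower": 100.0 * n_sh / n},
    )


def direction_tests_by_category(
    pad_table: pd.DataFrame, limits: tuple[str, ...] = ("min", "max")
) -> pd.DataFrame:
    """Binomial direction test per lineage category and range limit."""
    rows = []
    groups = [("all", pad_table)]
    if "category" in pad_table.columns:
        groups += list(pad_table.groupby("category"))
    for cat, sub in groups:
        for lim in limits:
            r = binomial_direction_test(sub[f"delta_{lim}"])
            rows.append({"category": cat, "limit": lim, "n": r.n,
                         "prop_shallower": r.statistic, "p_value": r.p_value,
                         **{k: v for k, v in r.extra.items()}})
    return pd.DataFrame(rows)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw p)."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


# ---------------------------------------------------------------------------
# cross-tree partition-rate comparison


@dataclass
class PartitionRateComparison:
    standardized: pd.DataFrame          # trees x categories, log10 standardized
    shapiro: pd.DataFrame
    kruskal: TestResult
    pairwise: pd.DataFrame


def compare_partition_rates(rates_by_tree: pd.DataFrame) -> PartitionRateComparison:
    """Compare lineage-category colonization rates across a tree sample.

    ``rates_by_tree`` has one row per tree and one column per category,
    holding that tree's posterior median rate for the category.  Within each
    tree all rates are divided by the tree's minimum (so the slowest
    category sits at exactly 1, log10 = 0), then log10-transformed.
    Normality per category is reported descriptively (Shapiro-Wilk); the
    omnibus test is Kruskal-Wallis over categories, followed by pairwise
    two-sided Wilcoxon rank-sum tests with Holm adjustment.
    """
    df = rates_by_tree.dropna(axis=1, how="all")
    dropped = sorted(set(rates_by_tree.columns) - set(df.columns))
    if dropped:
        warnings.warn(f"categories absent in all trees dropped: {dropped}")
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("need >= 2 categories and >= 2 trees")
    std = df.div(df.min(axis=1), axis=0)
    std = np.log10(std)

    sh_rows = []
    for c in std.columns:
        x = std[c].dropna()
        if len(x) >= 3 and np.ptp(x) > 0:
            w, p = stats.shapiro(x)
        else:
            w, p = np.nan, np.nan
        sh_rows.append({"category": c, "W": w, "p_value": p, "n": len(x)})
    shapiro = pd.DataFrame(sh_rows)

    samples = [std[c].dropna().to_numpy() for c in std.columns]
    H, p = stats.kruskal(*samples)
    kw = TestResult(float(H), float(p), int(sum(len(s) for s in samples)),
                    extra={"df": len(samples) - 1})

    pairs = []
    cats = list(std.columns)
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            a = std[cats[i]].dropna().to_numpy()
            b = std[cats[j]].dropna().to_numpy()
            u, pv = stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="auto")
            pairs.append({"a": cats[i], "b": cats[j], "U": float(u),
                          "p_value": float(pv)})
    pw = pd.DataFrame(pairs)
    pw["p_adjusted"] = holm_adjust(pw["p_value"])
    pw["significant"] = pw["p_adjusted"] < 0.05
    return PartitionRateComparison(std, shapiro, kw, pw)


# ---------------------------------------------------------------------------
# long-term trend regressions


def longterm_trend_regression(
    node_depth: np.ndarray,
    node_age: np.ndarray,
    categories,
    rate_classes,
    exclude_root: int | None = None,
    min_branches: int = 10,
    n_samples: int = 1000,
    seed: int = 0,
) -> dict[str, RegressionFit | None]:
    """Depth ~ age regressions per rate stratum with category covariates.

    Nodes (tips and internal, root excluded) are split into a *slow*
    stratum — constant plus decelerated rates, joined because decelerations
    are rare — and an *accelerated* stratum.  Within each stratum the model
    has a per-category intercept and age slope; categories with fewer than
    ``min_branches`` members in the stratum are excluded (logged in the
    returned fit's coefficient names simply by absence).  Ages are Ma before
    present, so a *positive* slope on age means depth decreasing toward the
    present... sign conventions: depth is log10 m, age increases into the
    past; a negative coefficient on age means shallower values at older
    ages.
    """
    depth = np.asarray(node_depth, dtype=float)
    age = np.asarray(node_age, dtype=float)
    cats = np.asarray(categories, dtype=object)
    rc = np.asarray(rate_classes, dtype=object)
    mask = np.ones(depth.size, dtype=bool)
    if exclude_root is not None:
        mask[exclude_root] = False
    strata = {
        "slow": mask & np.isin(rc, [RATE_CONSTANT, RATE_DECELERATED]),
        "accelerated": mask & (rc == RATE_ACCELERATED),
    }
    out: dict[str, RegressionFit | None] = {}
    for name, sel in strata.items():
        if sel.sum() < min_branches:
            warnings.warn(f"stratum {name!r} has too few nodes; skipped")
            out[name] = None
            continue
        sub_cats = cats[sel]
        counts = pd.Series(sub_cats).value_counts()
        keep_cats = [c for c in counts.index if counts[c] >= min_branches]
        keep = np.isin(sub_cats, keep_cats)
        if keep.sum() == 0 or len(keep_cats) == 0:
            out[name] = None
            continue
        sc = sub_cats[keep]
        X = np.zeros((keep.sum(), 2 * len(keep_cats)))
        names = []
        for k, c in enumerate(keep_cats):
            m = sc == c
            X[m, k] = 1.0
            X[m, len(keep_cats) + k] = age[sel][keep][m]
            names.append(f"intercept_{c}")
        names += [f"slope_age_{c}" for c in keep_cats]
        out[name] = bayesian_lm(X, depth[sel][keep], coef_names=names,
                                n_samples=n_samples, seed=seed)
    return out


def depth_vs_scalar_regression(
    max_depth: np.ndarray,
    scalars: np.ndarray,
    categories,
    exclude: tuple[str, ...] = ("ZS",),
    n_samples: int = 1000,
    seed: int = 0,
) -> RegressionFit:
    """Maximum depth predicted by the branch rate scalar, per category.

    Tests whether fast colonization (large r) thins out with depth.
    Categories in ``exclude`` are dropped (by default ZS, whose detected
    accelerations are too few to fit).  If no branch is accelerated at all
    the fit proceeds on the full set with a warning.
    """
    depth = np.asarray(max_depth, dtype=float)
    r = np.asarray(scalars, dtype=float)
    cats = np.asarray(categories, dtype=object)
    keep = ~np.isin(cats, list(exclude))
    if not np.any(r[keep] > 1.0):
        warnings.warn("no accelerated branches; fitting on the full set")
    depth, r, cats = depth[keep], r[keep], cats[keep]
    levels = [c for c in pd.unique(cats)]
    X = np.zeros((depth.size, 2 * len(levels)))
    names = []
    for k, c in enumerate(levels):
        m = cats == c
        X[m, k] = 1.0
        X[m, len(levels) + k] = r[m]
        names.append(f"intercept_{c}")
    names += [f"slope_r_{c}" for c in levels]
    if len(levels) == 1:
        X = np.column_stack([np.ones(depth.size), r])
        names = [f"intercept_{levels[0]}", f"slope_r_{levels[0]}"]
    # shrinkage keeps the fit proper when scalars barely vary (e.g. no
    # significant accelerations), where slope and intercept become collinear
    return bayesian_lm(X, depth, coef_names=names, n_samples=n_samples,
                       seed=seed, shrinkage_sd=30.0)


def pathwise_depth_association(
    tree: TimeTree,
    tip_depths,
    groups,
    facultative=None,
    lam: float | str = "estimate",
    min_tips: int = 3,
    n_samples: int = 1000,
    seed: int = 0,
) -> RegressionFit:
    """Current log depth ~ path-wise rate per group (PGLS, lambda estimated).

    The path-wise rate is the root-to-tip distance on the rate-scaled tree
    (``tree`` should carry the significant scalars).  Groups with fewer than
    ``min_tips`` tips get no slope of their own: their tips are pooled into
    a shared ``other`` intercept so the tree stays intact while the
    under-filled group is excluded from the association test.
    """
    y = np.asarray(
        tip_depths if not isinstance(tip_depths, dict)
        else [tip_depths[l] for l in tree.tip_labels], dtype=float)
    pw = tree.depths_from_root(use_scalars=True)[tree.tip_ids]
    codes = build_design_matrix(groups, facultative)
    counts = codes.sum(axis=0)
    keep_groups = [j for j in range(4) if counts[j] >= min_tips]
    names = [g for j, g in enumerate(("AS", "AC", "ZS", "ZC")) if j in keep_groups]
    C = codes[:, keep_groups]
    X = np.hstack([C, C * pw[:, None]])
    coef_names = [f"intercept_{g}" for g in names] + [f"slope_pw_{g}" for g in names]
    leftover = 1.0 - C.sum(axis=1)
    if np.any(leftover > 1e-9):
        X = np.column_stack([X, leftover])
        coef_names = coef_names + ["intercept_other"]
    # shrinkage keeps the fit proper when path-wise rates barely vary (an
    # ultrametric tree with no significant scalars is exactly collinear)
    return pgls_regression(tree, y, X, coef_names=coef_names, lam=lam,
                           n_samples=n_samples, seed=seed, use_scalars=False,
                           shrinkage_sd=30.0)
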