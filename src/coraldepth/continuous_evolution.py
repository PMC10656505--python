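"""Brownian-motion models of log-depth evolution on a time tree.

This module provides the continuous-trait machinery of the pipeline:

* the Brownian likelihood of tip values with Pagel's lambda, computed by
  Felsenstein pruning on a transformed tree (lambda multiplies the shared,
  off-diagonal part of the phylogenetic covariance while tip variances are
  preserved);
* Bayesian phylogenetic regression (PGLS) with group dummy coding,
  analytically marginalizing coefficients and the rate under a flat /
  Jeffreys prior and sampling lambda by Metropolis;
* the variable-rates (VR) model: a reversible-jump MCMC that places
  multiplicative scalars r on branches or whole clades, stretching
  (r > 1, accelerated change) or compressing (0 < r < 1, decelerated
  change) branch lengths relative to the single-rate Brownian background;
* a-priori partitioned local rates (one scalar per branch category);
* stepping-stone estimation of log marginal likelihoods, and Bayes-factor
  and posterior-crossing-zero significance helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .treekit import TimeTree

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# covariance construction


def tip_covariance(
    tree: TimeTree,
    scalars: np.ndarray | None = None,
    lam: float = 1.0,
    use_scalars: bool = True,
) -> np.ndarray:
    """Phylogenetic covariance of the tips under (scaled) Brownian motion.

    ``V[i, j]`` is the scaled root-to-MRCA path length of tips i and j;
    lambda multiplies the off-diagonal entries only, preserving tip
    variances.
    """
    s = tree.scalar if scalars is None else np.asarray(scalars, dtype=float)
    ln = tree.length * (s if use_scalars else 1.0)
    d = np.zeros(tree.n_nodes)
    for i in tree.preorder():
        p = tree.parent[i]
        if p >= 0:
            d[i] = d[p] + ln[i]
    tb = tree.tips_below()
    n = tree.n_tips
    V = np.zeros((n, n))
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            continue
        ch = tree.children[i]
        for a in range(len(ch)):
            for b in range(a + 1, len(ch)):
                ia, ib = tb[ch[a]], tb[ch[b]]
                V[np.ix_(ia, ib)] = d[i]
                V[np.ix_(ib, ia)] = d[i]
    diag = d[tree.tip_ids]
    if lam != 1.0:
        V *= lam
    V[np.diag_indices(n)] = diag
    return V


def _align_tip_values(tree: TimeTree, values) -> np.ndarray:
    """Accept a dict keyed by tip label or an array aligned to tip ids."""
    if isinstance(values, dict):
        labels = tree.tip_labels
        missing = [l for l in labels if l not in values]
        if missing:
            raise ValueError(f"missing tip values for {missing[:5]}")
        if len(values) != len(labels):
            extra = set(values) - set(labels)
            raise ValueError(f"values for unknown/duplicate tips: {sorted(extra)[:5]}")
        return np.array([float(values[l]) for l in labels])
    arr = np.asarray(values, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError("tip value array length != number of tips")
    return arr


# ---------------------------------------------------------------------------
# Brownian likelihood by pruning


def bm_loglik(
    tree: TimeTree,
    tip_values,
    sigma2: float,
    root_mean: float,
    lam: float = 1.0,
    use_scalars: bool = True,
) -> float:
    """Log density of tip values under (rate-scaled) Brownian motion.

    Computed by post-order Gaussian message passing ("pruning"), so cost is
    linear in the number of nodes.  The lambda transform is applied on branch
    lengths: internal branches are multiplied by lambda and each pendant
    branch is lengthened by (1 - lambda) times its tip's root-to-tip scaled
    depth, which scales off-diagonal covariance by lambda while leaving tip
    variances intact.
    """
    x = _align_tip_values(tree, tip_values)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    ln = tree.length * (tree.scalar if use_scalars else 1.0)
    if lam != 1.0:
        d = np.zeros(tree.n_nodes)
        for i in tree.preorder():
            p = tree.parent[i]
            if p >= 0:
                d[i] = d[p] + ln[i]
        ln = ln * lam
        for k, tip in enumerate(tree.tip_ids):
            ln[tip] += (1.0 - lam) * d[tip]

    mean = np.zeros(tree.n_nodes)
    var = np.zeros(tree.n_nodes)
    logz = 0.0
    tip_index = {t: k for k, t in enumerate(tree.tip_ids)}
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            mean[i], var[i] = x[tip_index[i]], 0.0
        else:
            ch = tree.children[i]
            m, v = mean[ch[0]], var[ch[0]] + sigma2 * ln[ch[0]]
            for c in ch[1:]:
                mc, vc = mean[c], var[c] + sigma2 * ln[c]
                tot = v + vc
                if tot <= 0:
                    raise ValueError(
                        "degenerate (zero-variance) sister branches: "
                        "likelihood undefined"
                    )
                logz += -0.5 * (LOG2PI + math.log(tot)) - (m - mc) ** 2 / (2 * tot)
                m = (m * vc + mc * v) / tot
                v = v * vc / tot
            mean[i], var[i] = m, v
    v_root = var[tree.root]
    if v_root <= 0:
        raise ValueError("degenerate tree: zero variance at root")
    logz += -0.5 * (LOG2PI + math.log(v_root)) \
        - (mean[tree.root] - root_mean) ** 2 / (2 * v_root)
    return logz


# ---------------------------------------------------------------------------
# GLS sufficient statistics and marginal likelihood


def _gls_stats(V: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Sufficient statistics for y ~ N(X beta, sigma2 V).

    ``ridge`` adds a conjugate shrinkage prior beta ~ N(0, sigma2 / ridge)
    per coefficient; 0 means a flat prior.  The returned S is the posterior
    residual sum, valid for either prior.
    """
    n, k = X.shape
    L = np.linalg.cholesky(V)
    Xs = np.linalg.solve(L, X)
    ys = np.linalg.solve(L, y)
    XtViX = Xs.T @ Xs + ridge * np.eye(k)
    XtViy = Xs.T @ ys
    ytViy = ys @ ys
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    beta_hat = np.linalg.solve(XtViX, XtViy)
    S = float(ytViy - beta_hat @ XtViy)
    return beta_hat, XtViX, S, logdetV


def gls_marginal_loglik(V: np.ndarray, X: np.ndarray, y: np.ndarray,
                        ridge: float = 0.0) -> float:
    """Log marginal likelihood of y ~ N(X beta, sigma2 V).

    Coefficients get a flat prior and sigma2 the Jeffreys prior 1/sigma2,
    both integrated out analytically.  Improper-prior constants are shared
    across models with the same n and k, so differences of this quantity are
    valid Metropolis ratios for anything else (lambda, branch scalars).
    """
    n, k = X.shape
    beta_hat, XtViX, S, logdetV = _gls_stats(V, X, y, ridge)
    if S <= 0:
        S = 1e-300
    nu = n - k
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("design is rank deficient")
    return (
        gammaln(nu / 2.0)
        - (nu / 2.0) * math.log(math.pi)
        - 0.5 * logdetV
        - 0.5 * logdetXtViX
        - (nu / 2.0) * math.log(S)
    )


def _mvn_draw(mean, cov, rng):
    """Multivariate normal draw tolerant of semidefinite covariances."""
    w, U = np.linalg.eigh((cov + cov.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return mean + (U * np.sqrt(w)) @ rng.normal(size=mean.size)


def _sample_beta_sigma2(V, X, y, rng, ridge: float = 0.0):
    """One conjugate posterior draw of (beta, sigma2) given V."""
    n, k = X.shape
    beta_hat, XtViX, S, _ = _gls_stats(V, X, y, ridge)
    nu = n - k
    sigma2 = S / rng.chisquare(nu)
    cov = np.linalg.inv(XtViX) * sigma2
    return _mvn_draw(beta_hat, cov, rng), sigma2


# ---------------------------------------------------------------------------
# design matrices

GROUPS = ("AS", "AC", "ZS", "ZC")


def build_design_matrix(
    groups,
    facultative=None,
    group_cols: tuple[str, ...] = GROUPS,
) -> np.ndarray:
    """Dummy coding of trait groups, with facultative species split 0.5/0.5.

    ``groups[i]`` is the primary group of tip i (one of AS/AC/ZS/ZC);
    ``facultative[i]`` is None, ``"symbiosis"`` or ``"coloniality"``.  A
    facultative species contributes 0.5 to its stated group and 0.5 to the
    group with the other state of the facultative trait (a colonial species
    facultative for symbiosis coded ZC gets 0.5 in ZC and 0.5 in AC).  Every
    row sums to 1 across the group columns.
    """
    col = {g: j for j, g in enumerate(group_cols)}
    X = np.zeros((len(groups), len(group_cols)))
    fac = facultative if facultative is not None else [None] * len(groups)
    for i, (g, f) in enumerate(zip(groups, fac)):
        if g not in col:
            raise ValueError(f"unknown group {g!r}")
        if f is None:
            X[i, col[g]] = 1.0
        else:
            if f == "symbiosis":
                other = ("Z" if g[0] == "A" else "A") + g[1]
            elif f == "coloniality":
                other = g[0] + ("C" if g[1] == "S" else "S")
            else:
                raise ValueError(f"unknown facultative trait {f!r}")
            X[i, col[g]] = 0.5
            X[i, col[other]] = 0.5
    return X


# ---------------------------------------------------------------------------
# regression fit container


@dataclass
class RegressionFit:
    """Posterior summary of a (phylogenetic) Bayesian regression."""

    coef_names: list[str]
    beta_samples: np.ndarray        # (S, k)
    sigma2_samples: np.ndarray      # (S,)
    lambda_samples: np.ndarray      # (S,) constant if lambda was fixed
    r_squared: float
    seed: int

    @property
    def coefficients(self) -> dict[str, float]:
        med = np.median(self.beta_samples, axis=0)
        return dict(zip(self.coef_names, med))

    @property
    def lam(self) -> float:
        return float(np.median(self.lambda_samples))

    def crossing_significance(self, name_or_index) -> tuple[float, bool]:
        j = (self.coef_names.index(name_or_index)
             if isinstance(name_or_index, str) else name_or_index)
        return posterior_crossing_significance(self.beta_samples[:, j])


def _gls_r_squared(V, X, y, beta):
    Li = np.linalg.cholesky(V)
    e = np.linalg.solve(Li, y - X @ beta)
    ones = np.linalg.solve(Li, np.ones_like(y))
    yw = np.linalg.solve(Li, y)
    ybar = (ones @ yw) / (ones @ ones)
    tot = np.linalg.solve(Li, y - ybar)
    denom = tot @ tot
    if denom <= 0:
        return 1.0
    return float(max(0.0, min(1.0, 1.0 - (e @ e) / denom)))


def pgls_regression(
    tree: TimeTree,
    response,
    design: np.ndarray,
    coef_names: list[str] | None = None,
    lam: float | str = "estimate",
    n_samples: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
    use_scalars: bool = True,
    lambda_proposal_sd: float = 0.15,
    shrinkage_sd: float | None = None,
) -> RegressionFit:
    """Bayesian PGLS with conjugate (beta, sigma2) and Metropolis lambda.

    With lambda fixed the sampler is exact (independent conjugate draws);
    with ``lam="estimate"`` a reflected random walk on [0, 1] samples lambda
    against the analytically marginalized likelihood, and (beta, sigma2)
    are drawn conjugately for each retained lambda.  ``shrinkage_sd`` puts a
    weakly-informative N(0, (shrinkage_sd * sigma)^2) prior on each
    coefficient, keeping the posterior proper for collinear designs (the
    default flat prior instead raises on rank deficiency).
    """
    y = _align_tip_values(tree, response)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    ridge = 0.0 if shrinkage_sd is None else 1.0 / shrinkage_sd ** 2
    if n != tree.n_tips:
        raise ValueError("design rows must align to tips")
    if shrinkage_sd is None and np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    if coef_names is None:
        coef_names = [f"b{j}" for j in range(k)]
    rng = np.random.default_rng(seed)

    V1 = tip_covariance(tree, lam=1.0, use_scalars=use_scalars)
    diag = np.diag(V1).copy()

    def V_of(lmb):
        V = V1 * lmb
        V[np.diag_indices(n)] = diag
        return V

    if lam != "estimate":
        lam_f = float(lam)
        V = V_of(lam_f)
        betas = np.empty((n_samples, k))
        sig = np.empty(n_samples)
        for s in range(n_samples):
            betas[s], sig[s] = _sample_beta_sigma2(V, X, y, rng, ridge)
        lams = np.full(n_samples, lam_f)
        r2 = _gls_r_squared(V, X, y, np.median(betas, axis=0))
        return RegressionFit(coef_names, betas, sig, lams, r2, seed)

    lmb = 0.5
    ll = gls_marginal_loglik(V_of(lmb), X, y, ridge)
    lams, betas, sig = [], [], []
    for it in range(n_samples + burn_in):
        prop = lmb + rng.normal(0.0, lambda_proposal_sd)
        prop = abs(prop)
        if prop > 1.0:
            prop = 2.0 - prop
        prop = min(max(prop, 0.0), 1.0)
        ll_p = gls_marginal_loglik(V_of(prop), X, y, ridge)
        if math.log(rng.random() + 1e-300) < ll_p - ll:
            lmb, ll = prop, ll_p
        if it >= burn_in:
            b, s2 = _sample_beta_sigma2(V_of(lmb), X, y, rng, ridge)
            lams.append(lmb)
            betas.append(b)
            sig.append(s2)
    betas = np.array(betas)
    lams = np.array(lams)
    r2 = _gls_r_squared(V_of(float(np.median(lams))), X, y, np.median(betas, axis=0))
    return RegressionFit(coef_names, betas, np.array(sig), lams, r2, seed)


def bayesian_lm(
    X: np.ndarray, y: np.ndarray, coef_names=None,
    n_samples: int = 1000, seed: int = 0, shrinkage_sd: float | None = None,
) -> RegressionFit:
    """Ordinary (non-phylogenetic) Bayesian linear regression.

    Conjugate sampler; equivalent to PGLS with an identity covariance.  Used
    for node-level trend regressions where rows are tree nodes rather than
    exchangeable tips.  With the default flat prior a rank-deficient design
    is an error; passing ``shrinkage_sd`` (a weakly-informative prior sd per
    coefficient, in units of the residual sd) makes the posterior proper
    even for collinear designs, leaving well-identified coefficients
    essentially untouched.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    ridge = 0.0 if shrinkage_sd is None else 1.0 / shrinkage_sd ** 2
    if shrinkage_sd is None and np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    if coef_names is None:
        coef_names = [f"b{j}" for j in range(k)]
    rng = np.random.default_rng(seed)
    V = np.eye(n)
    betas = np.empty((n_samples, k))
    sig = np.empty(n_samples)
    for s in range(n_samples):
        betas[s], sig[s] = _sample_beta_sigma2(V, X, y, rng, ridge)
    r2 = _gls_r_squared(V, X, y, np.median(betas, axis=0))
    return RegressionFit(list(coef_names), betas, sig, np.zeros(n_samples), r2, seed)


# ---------------------------------------------------------------------------
# variable-rates reversible-jump MCMC


@dataclass
class VRConfig:
    """Chain settings for the variable-rates sampler."""

    n_iter: int = 20000
    burn_in: int = 4000
    thin: int = 20
    seed: int = 0
    clade_moves: bool = True
    log_r_bounds: tuple[float, float] = (math.log(1e-2), math.log(1e2))
    geometric_p: float = 0.5      # prior on the number of placed scalars
    update_sd: float = 0.7        # random-walk sd on log r
    lam: float = 1.0
    record_conditional: bool = True


@dataclass
class PosteriorChain:
    """Thinned posterior sample from the VR (or partitioned) model."""

    tree: TimeTree
    scalars: np.ndarray           # (S, n_nodes) effective r per branch
    beta: np.ndarray              # (S, k) conjugate coefficient draws
    sigma2: np.ndarray            # (S,)
    loglik: np.ndarray            # (S,) conditional BM log likelihood
    marginal_ll: np.ndarray       # (S,) analytically marginalized
    n_scalars: np.ndarray         # (S,)
    coef_names: list[str]
    seed: int
    accept_rate: float
    lam: float = 1.0

    def to_frame(self):
        import pandas as pd
        rows = []
        for s in range(self.scalars.shape[0]):
            rows.append({"sample": s, "sigma2": self.sigma2[s],
                         "loglik": self.loglik[s], "k": self.n_scalars[s]})
        return pd.DataFrame(rows)


class _VRState:
    """Current assignment of multiplicative scalars to branches/clades."""

    def __init__(self, tree: TimeTree, clade_moves: bool):
        self.tree = tree
        targets = [("branch", int(i)) for i in range(tree.n_nodes - 1)]
        if clade_moves:
            targets += [("clade", int(i)) for i in range(tree.n_nodes - 1)
                        if not tree.is_tip[i]]
        self.targets = targets
        self.assigned: dict[tuple[str, int], float] = {}
        self._clade_cache: dict[int, np.ndarray] = {}

    def branches_of(self, target):
        kind, node = target
        if kind == "branch":
            return np.array([node])
        if node not in self._clade_cache:
            nodes = self.tree.clade_nodes(node)
            self._clade_cache[node] = nodes  # includes the stem branch
        return self._clade_cache[node]

    def effective_scalars(self) -> np.ndarray:
        r = np.ones(self.tree.n_nodes)
        for target, logr in self.assigned.items():
            b = self.branches_of(target)
            r[b] *= math.exp(logr)
        return r


def vr_rjmcmc(
    tree: TimeTree,
    response,
    design: np.ndarray | None = None,
    config: VRConfig | None = None,
    coef_names: list[str] | None = None,
) -> PosteriorChain:
    """Reversible-jump MCMC over branch/clade rate scalars.

    The model is Brownian motion whose branch lengths are multiplied by the
    product of all scalars covering the branch.  Coefficients (the root mean,
    or a regression design) and the background rate sigma2 are marginalized
    analytically, so the chain moves only in scalar space: birth (place a
    scalar on a free branch or clade, value drawn from its log-uniform
    prior), death, and a random-walk value update.  The number of placed
    scalars has a geometric prior.  Conjugate (beta, sigma2) draws and the
    conditional Brownian log likelihood are recorded for each retained
    sample.
    """
    cfg = config or VRConfig()
    y = _align_tip_values(tree, response)
    if np.ptp(y) == 0:
        raise ValueError("response is constant: zero variance")
    if design is None:
        X = np.ones((tree.n_tips, 1))
        coef_names = coef_names or ["root_mean"]
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        coef_names = coef_names or [f"b{j}" for j in range(X.shape[1])]
    rng = np.random.default_rng(cfg.seed)
    state = _VRState(tree, cfg.clade_moves)
    T = len(state.targets)
    a, b = cfg.log_r_bounds
    width = b - a
    gp = cfg.geometric_p

    def marginal(scals):
        V = tip_covariance(tree, scalars=scals, lam=cfg.lam)
        return gls_marginal_loglik(V, X, y)

    scals = state.effective_scalars()
    ll = marginal(scals)

    def move_probs(k):
        pb = 0.4 if k < T else 0.0
        pd = 0.4 if k > 0 else 0.0
        pu = 0.2 if k > 0 else 0.0
        tot = pb + pd + pu
        return pb / tot, pd / tot, pu / tot

    n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
    S_r = np.empty((n_keep, tree.n_nodes))
    S_beta = np.empty((n_keep, X.shape[1]))
    S_sig = np.empty(n_keep)
    S_ll = np.empty(n_keep)
    S_mll = np.empty(n_keep)
    S_k = np.empty(n_keep, dtype=int)
    kept = 0
    accepted = 0

    for it in range(cfg.n_iter):
        k = len(state.assigned)
        pb, pd_, pu = move_probs(k)
        u = rng.random()
        if u < pb:  # birth
            free = [t for t in state.targets if t not in state.assigned]
            target = free[rng.integers(len(free))]
            logr = rng.uniform(a, b)
            state.assigned[target] = logr
            new_scals = state.effective_scalars()
            ll_new = marginal(new_scals)
            pb2, pd2, _ = move_probs(k + 1)
            log_acc = (ll_new - ll
                       + math.log(1 - gp)                      # prior on k
                       + math.log(k + 1) - math.log(T - k)     # set prior
                       + math.log(pd2) - math.log(k + 1)       # reverse death
                       - (math.log(pb) - math.log(T - k)))     # forward birth
            if math.log(rng.random() + 1e-300) < log_acc:
                ll, scals = ll_new, new_scals
                accepted += 1
            else:
                del state.assigned[target]
        elif u < pb + pd_:  # death
            keys = list(state.assigned)
            target = keys[rng.integers(len(keys))]
            old = state.assigned.pop(target)
            new_scals = state.effective_scalars()
            ll_new = marginal(new_scals)
            pb2, _, _ = move_probs(k - 1)
            log_acc = (ll_new - ll
                       - math.log(1 - gp)
                       - (math.log(k) - math.log(T - k + 1))
                       + math.log(pb2) - math.log(T - k + 1)
                       - (math.log(pd_) - math.log(k)))
            if math.log(rng.random() + 1e-300) < log_acc:
                ll, scals = ll_new, new_scals
                accepted += 1
            else:
                state.assigned[target] = old
        else:  # value update
            keys = list(state.assigned)
            target = keys[rng.integers(len(keys))]
            old = state.assigned[target]
            prop = old + rng.normal(0.0, cfg.update_sd)
            if a <= prop <= b:
                state.assigned[target] = prop
                new_scals = state.effective_scalars()
                ll_new = marginal(new_scals)
                if math.log(rng.random() + 1e-300) < ll_new - ll:
                    ll, scals = ll_new, new_scals
                    accepted += 1
                else:
                    state.assigned[target] = old
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            V = tip_covariance(tree, scalars=scals, lam=cfg.lam)
            beta, s2 = _sample_beta_sigma2(V, X, y, rng)
            S_r[kept] = scals
            S_beta[kept] = beta
            S_sig[kept] = s2
            S_mll[kept] = ll
            S_k[kept] = len(state.assigned)
            if cfg.record_conditional and design is None:
                S_ll[kept] = bm_loglik(tree.with_scalars(scals), y,
                                       s2, float(beta[0]), lam=cfg.lam)
            else:
                S_ll[kept] = np.nan
            kept += 1

    return PosteriorChain(
        tree=tree, scalars=S_r[:kept], beta=S_beta[:kept], sigma2=S_sig[:kept],
        loglik=S_ll[:kept], marginal_ll=S_mll[:kept], n_scalars=S_k[:kept],
        coef_names=coef_names, seed=cfg.seed,
        accept_rate=accepted / max(cfg.n_iter, 1), lam=cfg.lam,
    )



def vr_rjmcmc_chains(
    tree: TimeTree,
    response,
    design: np.ndarray | None = None,
    config: VRConfig | None = None,
    n_chains: int = 3,
) -> list[PosteriorChain]:
    """Run several independent VR chains (seed-offset) for diagnostics.

    Three chains by default; combine their scalar samples for inference and
    feed per-chain traces to :func:`convergence_diagnostics`.
    """
    cfg = config or VRConfig()
    out = []
    for c in range(n_chains):
        cc = VRConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * c})
        out.append(vr_rjmcmc(tree, response, design, cc))
    return out


def convergence_diagnostics(chains: list[np.ndarray]) -> dict:
    """Effective sample size and split-chain R-hat for a scalar trace.

    ``chains`` is a list of 1-d sample arrays (one per independent chain);
    a single chain is split in half.  Uses arviz's rank-normalized
    estimators.
    """
    import arviz as az

    arr = np.asarray(chains, dtype=float)
    if arr.ndim == 1:
        half = arr.size // 2
        arr = np.stack([arr[:half], arr[half:2 * half]])
    data = az.convert_to_dataset(arr[:, :, None] if arr.ndim == 2 else arr)
    ess = float(az.ess(data)["x"].values.ravel()[0])
    rhat = float(az.rhat(data)["x"].values.ravel()[0])
    return {"ess": ess, "r_hat": rhat}

RATE_ACCELERATED = "accelerated"
RATE_CONSTANT = "constant"
RATE_DECELERATED = "decelerated"


def summarize_scaled_tree(
    chain: PosteriorChain,
    presence_threshold: float = 0.5,
    magnitude_threshold: float = 2.0,
    compression_threshold: float | None = None,
) -> tuple[TimeTree, np.ndarray]:
    """Median scaled tree with the significance rule applied per branch.

    A branch keeps its posterior-median scalar only if it is stretched or
    compressed in more than ``presence_threshold`` of the posterior sample
    and the median scalar magnitude passes the threshold (> 2 for stretches;
    symmetrically < 1/2 for compressions unless ``compression_threshold``
    overrides it); otherwise r is reset to 1.  Also returns the per-branch
    rate class (accelerated / constant / decelerated).
    """
    if chain.scalars.shape[0] == 0:
        raise ValueError("empty chain")
    if compression_threshold is None:
        compression_threshold = 1.0 / magnitude_threshold
    r = chain.scalars
    scaled_frac = np.mean(np.abs(np.log(r)) > 1e-12, axis=0)
    med = np.median(r, axis=0)
    keep = (scaled_frac > presence_threshold) & (
        (med > magnitude_threshold) | (med < compression_threshold)
    )
    out = np.ones(chain.tree.n_nodes)
    out[keep] = med[keep]
    out[chain.tree.root] = 1.0
    classes = np.full(chain.tree.n_nodes, RATE_CONSTANT, dtype=object)
    classes[out > 1.0] = RATE_ACCELERATED
    classes[out < 1.0] = RATE_DECELERATED
    return chain.tree.with_scalars(out), classes


def partitioned_rates(
    tree: TimeTree,
    response,
    branch_partition,
    config: VRConfig | None = None,
    design: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Posterior local rate per a-priori branch category.

    ``branch_partition`` assigns one category label to every non-root node
    (branch).  A single scalar per category multiplies all its branch
    lengths; categories are sampled jointly by random-scan Metropolis on the
    marginalized likelihood.  Categories with no branches are dropped with a
    warning.  Only rate ratios are strongly identified (the overall scale
    trades off against sigma2, which is marginalized), matching the
    downstream use where per-tree rates are standardized by their minimum.
    """
    cfg = config or VRConfig(n_iter=4000, burn_in=1000, thin=5)
    y = _align_tip_values(tree, response)
    part = np.asarray(branch_partition, dtype=object)
    if part.shape[0] == tree.n_nodes:
        part = part[: tree.n_nodes - 1]
    if part.shape[0] != tree.n_nodes - 1:
        raise ValueError("branch_partition must label every non-root node")
    cats = [c for c in pd_unique(part)]
    if design is None:
        X = np.ones((tree.n_tips, 1))
    else:
        X = np.asarray(design, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    a, b = cfg.log_r_bounds
    idx = {c: np.flatnonzero(part == c) for c in cats}
    empty = [c for c in cats if idx[c].size == 0]
    if empty:
        warnings.warn(f"empty categories dropped: {empty}")
        cats = [c for c in cats if idx[c].size]
    logr = {c: 0.0 for c in cats}

    def scal_vec():
        r = np.ones(tree.n_nodes)
        for c in cats:
            r[idx[c]] = math.exp(logr[c])
        return r

    def marginal():
        V = tip_covariance(tree, scalars=scal_vec(), lam=cfg.lam)
        return gls_marginal_loglik(V, X, y)

    ll = marginal()
    n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
    out = {c: np.empty(n_keep) for c in cats}
    kept = 0
    for it in range(cfg.n_iter):
        c = cats[rng.integers(len(cats))]
        old = logr[c]
        prop = old + rng.normal(0.0, cfg.update_sd)
        if a <= prop <= b:
            logr[c] = prop
            ll_new = marginal()
            if math.log(rng.random() + 1e-300) < ll_new - ll:
                ll = ll_new
            else:
                logr[c] = old
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            for cc in cats:
                out[cc][kept] = math.exp(logr[cc])
            kept += 1
    return {c: v[:kept] for c, v in out.items()}


def pd_unique(arr):
    """Order-preserving unique (first occurrence order)."""
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


# ---------------------------------------------------------------------------
# stepping-stone marginal likelihood


@dataclass
class SteppingStoneModel:
    """Adapter exposing what the stepping-stone sampler needs.

    ``sample_prior(rng) -> theta`` (1-d array), ``log_prior(theta)`` and
    ``log_likelihood(theta)``; ``proposal_sd`` scales the random walk used
    within each stone's power posterior.
    """

    sample_prior: object
    log_prior: object
    log_likelihood: object
    proposal_sd: float = 1.0


@dataclass
class MarginalLikelihood:
    logml: float
    n_stones: int
    iters_per_stone: int
    seed: int


def stepping_stone_logml(
    model: SteppingStoneModel,
    n_stones: int = 32,
    iters_per_stone: int = 400,
    seed: int = 0,
    beta_shape: float = 0.4,
) -> MarginalLikelihood:
    """Stepping-stone estimate of the log marginal likelihood (nats).

    The temperature ladder takes the standard Beta(0.4, 1)-quantile spacing,
    concentrating stones near the prior.  Each ratio between consecutive
    powers is estimated by importance weighting samples drawn from the lower
    power posterior; the beta=0 stone samples the prior directly and higher
    stones use a random-walk Metropolis chain seeded from the previous stone.
    """
    rng = np.random.default_rng(seed)
    betas = (np.arange(n_stones + 1) / n_stones) ** (1.0 / beta_shape)
    # stone 0: prior samples
    theta = np.atleast_1d(np.asarray(model.sample_prior(rng), dtype=float))
    d = theta.size
    logml = 0.0
    samples_ll = np.empty(iters_per_stone)
    for k in range(1, n_stones + 1):
        b_lo, b_hi = betas[k - 1], betas[k]
        if b_lo == 0.0:
            for i in range(iters_per_stone):
                th = np.atleast_1d(np.asarray(model.sample_prior(rng), dtype=float))
                samples_ll[i] = model.log_likelihood(th)
            theta = th
            lp = model.log_prior(theta)
            llik = samples_ll[-1]
        else:
            lp = model.log_prior(theta)
            llik = model.log_likelihood(theta)
            for i in range(iters_per_stone):
                prop = theta + rng.normal(0.0, model.proposal_sd, size=d)
                lp_p = model.log_prior(prop)
                if np.isfinite(lp_p):
                    ll_p = model.log_likelihood(prop)
                    if (math.log(rng.random() + 1e-300)
                            < lp_p + b_lo * ll_p - lp - b_lo * llik):
                        theta, lp, llik = prop, lp_p, ll_p
                samples_ll[i] = llik
        finite = samples_ll[np.isfinite(samples_ll)]
        if finite.size == 0:
            raise ValueError("likelihood is zero everywhere sampled")
        logml += logsumexp((b_hi - b_lo) * finite) - math.log(finite.size)
    return MarginalLikelihood(float(logml), n_stones, iters_per_stone, seed)


# ---------------------------------------------------------------------------
# model comparison


@dataclass
class ModelComparison:
    logml_complex: float
    logml_simple: float

    @property
    def log_bf(self) -> float:
        return 2.0 * (self.logml_complex - self.logml_simple)

    @property
    def evidence(self) -> str:
        bf = self.log_bf
        if bf > 10:
            return "very strong"
        if bf > 2:
            return "positive"
        if bf < -2:
            return "favors simple"
        return "none"

    def to_dict(self):
        return {
            "logml_complex": self.logml_complex,
            "logml_simple": self.logml_simple,
            "log_bf": self.log_bf,
            "evidence": self.evidence,
        }


def log_bayes_factor(logml_complex: float, logml_simple: float) -> ModelComparison:
    """2 x (complex - simple) in nats, with the usual evidence labels.

    Some published descriptions of this comparison print the subtraction in
    the opposite order while still reading BF > 2 as support for the complex
    model; both marginal likelihoods are therefore kept in the report so the
    orientation is unambiguous.
    """
    if not (math.isfinite(logml_complex) and math.isfinite(logml_simple)):
        raise ValueError("marginal likelihoods must be finite")
    return ModelComparison(logml_complex, logml_simple)


def posterior_crossing_significance(samples, alpha: float = 0.05) -> tuple[float, bool]:
    """Proportion of a posterior sample crossing zero, and an alpha flag.

    Reports min(P(x < 0), P(x > 0)); the quantity is "significant" when the
    smaller tail is below ``alpha`` (default 0.05).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 posterior samples")
    p = min(float(np.mean(x < 0)), float(np.mean(x > 0)))
    return p, p < alpha
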