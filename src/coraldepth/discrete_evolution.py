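"""Correlated evolution of photosymbiosis and coloniality.

The two binary traits are modelled jointly as a 4-state continuous-time
Markov chain over {AS, AC, ZS, ZC} (azooxanthellate/zooxanthellate x
solitary/colonial) in which the two dual-transition rates — both traits
changing in a single instant — are fixed to zero, leaving eight free rates.
The module computes the pruning likelihood of tip states, fits the rates by
MCMC under exponential priors whose mean carries a uniform(0, 10)
hyperprior, and produces per-node marginal posterior state probabilities
(median across rate draws, renormalized).

A rate-switching ("covarion") extension doubling the state space with a
hidden on/off class is available behind ``covarion=True``; the default is
the plain dependent model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .treekit import TimeTree
from .synthetic_data import STATES, DUAL_PAIRS, validate_rate_matrix, stationary_distribution

#: the eight free transitions, in a fixed reporting order
RATE_KEYS = (
    ("AS", "AC"), ("AC", "AS"),
    ("AS", "ZS"), ("ZS", "AS"),
    ("AC", "ZC"), ("ZC", "AC"),
    ("ZS", "ZC"), ("ZC", "ZS"),
)
_IDX = {s: i for i, s in enumerate(STATES)}


def build_rate_matrix(rates) -> np.ndarray:
    """Assemble the 4-state generator from the eight free rates.

    ``rates`` is a mapping keyed by (from, to) label pairs or a sequence in
    ``RATE_KEYS`` order.  Dual transitions stay zero; diagonals make rows
    sum to zero.
    """
    if not isinstance(rates, dict):
        rates = dict(zip(RATE_KEYS, rates))
    Q = np.zeros((4, 4))
    for (a, b), v in rates.items():
        if (a, b) not in RATE_KEYS:
            raise ValueError(f"transition {a}->{b} is not a free rate")
        if v < 0:
            raise ValueError("rates must be >= 0")
        Q[_IDX[a], _IDX[b]] = v
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probs(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """P(t) for every branch length at once, via eigendecomposition.

    Falls back to scipy's expm per branch when the generator is defective.
    Rows are clipped and renormalized to be stochastic to 1e-12.
    """
    t = np.asarray(t, dtype=float)
    n = Q.shape[0]
    try:
        w, U = np.linalg.eig(Q)
        Ui = np.linalg.inv(U)
        E = np.exp(np.multiply.outer(t, w))  # (m, n)
        P = np.einsum("ij,mj,jk->mik", U, E, Ui)
        P = np.real(P)
        if not np.all(np.isfinite(P)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * ti) for ti in t])
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _tip_partial(state, n_states: int) -> np.ndarray:
    """Partial likelihood row for a tip: index, label, or ambiguity vector."""
    v = np.zeros(n_states)
    if isinstance(state, str):
        v[_IDX[state]] = 1.0
    elif np.ndim(state) == 0:
        v[int(state)] = 1.0
    else:
        arr = np.asarray(state, dtype=float)
        if arr.size != n_states:
            raise ValueError("ambiguity vector has wrong length")
        v[:] = arr
    return v


def _root_distribution(Q, root) -> np.ndarray:
    if isinstance(root, str):
        if root == "stationary":
            return stationary_distribution(Q)
        if root == "uniform":
            return np.full(Q.shape[0], 1.0 / Q.shape[0])
        raise ValueError(f"unknown root option {root!r}")
    pi = np.asarray(root, dtype=float)
    if pi.size != Q.shape[0] or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("root distribution must be a probability vector")
    return pi


def _partials_down(tree: TimeTree, tip_states: dict, P: np.ndarray, n_states: int):
    """Post-order partial likelihoods with per-node log scaling."""
    D = np.empty((tree.n_nodes, n_states))
    logscale = 0.0
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            D[i] = _tip_partial(tip_states[tree.labels[i]], n_states)
        else:
            row = np.ones(n_states)
            for c in tree.children[i]:
                row *= P[c] @ D[c]
            m = row.max()
            if m <= 0:
                return D, -math.inf
            D[i] = row / m
            logscale += math.log(m)
    return D, logscale


def correlated_loglik(
    tree: TimeTree, tip_states: dict, Q: np.ndarray, root="stationary"
) -> float:
    """Pruning log likelihood of tip states under the 4-state chain.

    ``tip_states`` maps tip label to a state (index or label) or to a
    4-vector of ambiguity weights (facultative species spread mass over
    their two compatible states).  ``root`` selects the root state
    distribution: "stationary" (default), "uniform", or an explicit vector
    (a point mass is allowed).
    """
    Q = validate_rate_matrix(Q)
    missing = [l for l in tree.tip_labels if l not in tip_states]
    if missing:
        raise ValueError(f"tips without a state: {missing[:5]}")
    pi = _root_distribution(Q, root)
    P = transition_probs(Q, tree.length)
    D, logscale = _partials_down(tree, tip_states, P, 4)
    if not np.isfinite(logscale):
        return -math.inf
    like = float(pi @ D[tree.root])
    if like <= 0:
        return -math.inf
    return math.log(like) + logscale


# ---------------------------------------------------------------------------
# covarion (hidden rate-class) extension


def covarion_generator(Q: np.ndarray, switch_on_off: float, switch_off_on: float) -> np.ndarray:
    """8-state generator: visible 4-state chain x hidden on/off class.

    In the "on" class the traits evolve by Q; in the "off" class trait
    change is frozen; the hidden class toggles at the two switch rates.
    State order: the four visible states in the on class, then off.
    """
    Q = validate_rate_matrix(Q)
    Z = np.zeros((4, 4))
    I4 = np.eye(4)
    top = np.hstack([Q - switch_on_off * I4 + np.diag(np.zeros(4)), switch_on_off * I4])
    bot = np.hstack([switch_off_on * I4, Z - switch_off_on * I4])
    G = np.vstack([top, bot])
    # fix diagonals so rows sum to zero exactly
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=1))
    return G


def covarion_loglik(
    tree: TimeTree, tip_states: dict, Q: np.ndarray,
    switch_on_off: float, switch_off_on: float, root: str = "stationary",
) -> float:
    """Likelihood under the covarion extension; tips are ambiguous over the
    hidden class (a tip observed as AS may be on-AS or off-AS)."""
    G = covarion_generator(Q, switch_on_off, switch_off_on)
    if root == "stationary":
        pi = stationary_distribution(G)
    else:
        pi = np.full(8, 1.0 / 8)
    P = transition_probs(G, tree.length)
    tips8 = {}
    for lbl in tree.tip_labels:
        v4 = _tip_partial(tip_states[lbl], 4)
        tips8[lbl] = np.concatenate([v4, v4])
    D, logscale = _partials_down(tree, tips8, P, 8)
    if not np.isfinite(logscale):
        return -math.inf
    like = float(pi @ D[tree.root])
    return math.log(like) + logscale if like > 0 else -math.inf


# ---------------------------------------------------------------------------
# Bayesian fit


@dataclass
class DiscreteChainConfig:
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    proposal_sd: float = 0.5      # on log rate
    hyper_proposal_sd: float = 1.0
    rj: bool = False              # reversible-jump zeroing of rates
    prior_only: bool = False      # sample the prior (likelihood off)
    root: str = "stationary"


@dataclass
class DiscretePosterior:
    rates: np.ndarray             # (S, 8) in RATE_KEYS order
    hyper_mean: np.ndarray        # (S,)
    loglik: np.ndarray
    seed: int
    accept_rate: float

    def rate_medians(self) -> dict:
        med = np.median(self.rates, axis=0)
        return {k: float(v) for k, v in zip(RATE_KEYS, med)}


def fit_discrete_mcmc(
    tree: TimeTree, tip_states: dict, config: DiscreteChainConfig | None = None
) -> DiscretePosterior:
    """MCMC over the eight transition rates.

    Each rate has an exponential prior whose mean m carries a uniform(0, 10)
    hyperprior.  Rates are updated one at a time by a log-scale random walk
    (with the Jacobian term), the hypermean by a reflected walk on (0, 10).
    With ``rj=True`` rates can additionally be switched off (set to zero)
    and on by a reversible-jump pair of moves with the prior as proposal.
    ``prior_only=True`` drops the likelihood term, for prior-predictive
    checks.  All tips in one state only weakly identifies the rates; that is
    reported as a warning, not an error.
    """
    cfg = config or DiscreteChainConfig()
    vals = [(_tip_partial(tip_states[l], 4)).argmax() for l in tree.tip_labels]
    if len(set(vals)) == 1:
        warnings.warn("all tips share one state: rates are weakly identified")
    rng = np.random.default_rng(cfg.seed)

    def loglik(rates):
        if cfg.prior_only:
            return 0.0
        Q = build_rate_matrix(rates)
        return correlated_loglik(tree, tip_states, Q, root=cfg.root)

    def log_prior(rates, m, active):
        # exponential(mean m) on active rates; inactive (RJ-zeroed) excluded
        if not 0.0 < m < 10.0:
            return -math.inf
        k = active.sum()
        return -k * math.log(m) - rates[active].sum() / m

    m = 1.0
    rates = np.full(8, 0.5)
    active = np.ones(8, dtype=bool)
    ll = loglik(rates)
    lp = log_prior(rates, m, active)
    n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
    S_rates = np.empty((n_keep, 8))
    S_m = np.empty(n_keep)
    S_ll = np.empty(n_keep)
    kept = 0
    accepted = 0
    n_moves = 0

    for it in range(cfg.n_iter):
        # rate updates (random single-rate scan)
        j = rng.integers(8)
        n_moves += 1
        if active[j]:
            old = rates[j]
            prop = old * math.exp(rng.normal(0.0, cfg.proposal_sd))
            rates[j] = prop
            ll_new = loglik(rates)
            lp_new = log_prior(rates, m, active)
            # Jacobian of the log-scale walk: prop/old
            if math.log(rng.random() + 1e-300) < (
                ll_new + lp_new - ll - lp + math.log(prop / old)
            ):
                ll, lp = ll_new, lp_new
                accepted += 1
            else:
                rates[j] = old
        # hypermean update
        prop_m = m + rng.normal(0.0, cfg.hyper_proposal_sd)
        if prop_m < 0:
            prop_m = -prop_m
        if prop_m > 10:
            prop_m = 20 - prop_m
        lp_new = log_prior(rates, prop_m, active)
        if math.log(rng.random() + 1e-300) < lp_new - lp:
            m, lp = prop_m, lp_new
        # reversible-jump toggle
        if cfg.rj:
            j = rng.integers(8)
            if active[j]:
                old = rates[j]
                active[j] = False
                rates[j] = 0.0
                ll_new = loglik(rates)
                lp_new = log_prior(rates, m, active)
                # proposal for reverse move draws from the prior, so the
                # value density cancels against the prior term
                if math.log(rng.random() + 1e-300) < ll_new + lp_new - ll - lp \
                        - (-math.log(m) - old / m):
                    ll, lp = ll_new, lp_new
                else:
                    active[j] = True
                    rates[j] = old
            else:
                new = rng.exponential(m)
                active[j] = True
                rates[j] = new
                ll_new = loglik(rates)
                lp_new = log_prior(rates, m, active)
                if math.log(rng.random() + 1e-300) < ll_new + lp_new - ll - lp \
                        + (-math.log(m) - new / m):
                    ll, lp = ll_new, lp_new
                else:
                    active[j] = False
                    rates[j] = 0.0
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            S_rates[kept] = rates
            S_m[kept] = m
            S_ll[kept] = ll
            kept += 1

    return DiscretePosterior(S_rates[:kept], S_m[:kept], S_ll[:kept],
                             cfg.seed, accepted / max(n_moves, 1))


# ---------------------------------------------------------------------------
# marginal node state posteriors


def _node_marginals_once(tree: TimeTree, tip_states: dict, Q: np.ndarray, root):
    """Marginal state probability of every node for one rate draw (up-down)."""
    pi = _root_distribution(Q, root)
    P = transition_probs(Q, tree.length)
    D, logscale = _partials_down(tree, tip_states, P, 4)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under these rates")
    # M[c] = P_c @ D_c  (message from child c into its parent)
    M = np.empty_like(D)
    for c in range(tree.n_nodes - 1):
        M[c] = P[c] @ D[c]
    U = np.empty_like(D)
    U[tree.root] = pi
    for i in tree.preorder():
        if tree.is_tip[i]:
            continue
        for c in tree.children[i]:
            sib = np.ones(4)
            for b in tree.children[i]:
                if b != c:
                    sib *= M[b]
            up = U[i] * sib
            U[c] = up @ P[c]
    G = U * D
    tot = G.sum(axis=1, keepdims=True)
    tot[tot <= 0] = 1.0
    return G / tot


def node_state_posteriors(
    tree: TimeTree,
    tip_states: dict,
    rate_samples: np.ndarray | DiscretePosterior,
    root: str = "stationary",
    max_samples: int = 200,
) -> np.ndarray:
    """Per-node posterior probability of the four combined states.

    For each retained rate draw the exact marginal node probabilities are
    computed by an up-down pruning pass; the across-draw summary is the
    median probability per state, renormalized so each node's four values
    sum to one (medians alone do not).
    Returns an (n_nodes, 4) array in STATES order.
    """
    R = rate_samples.rates if isinstance(rate_samples, DiscretePosterior) else \
        np.asarray(rate_samples, dtype=float)
    if R.ndim == 1:
        R = R[None, :]
    if R.shape[0] == 0:
        raise ValueError("empty chain")
    if R.shape[0] > max_samples:
        sel = np.linspace(0, R.shape[0] - 1, max_samples).astype(int)
        R = R[sel]
    probs = np.empty((R.shape[0], tree.n_nodes, 4))
    for s in range(R.shape[0]):
        Q = build_rate_matrix(R[s])
        probs[s] = _node_marginals_once(tree, tip_states, Q, root)
    med = np.median(probs, axis=0)
    tot = med.sum(axis=1, keepdims=True)
    tot[tot <= 0] = 1.0
    return med / tot
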