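"""Seed-deterministic generators for every input the pipeline consumes.

The generators emulate the statistical structure the downstream analyses
assume for scleractinian corals:

* a birth–death time tree conditioned on a fixed number of extant tips;
* two correlated binary traits (photosymbiosis, coloniality) evolved as a
  4-state continuous-time Markov chain in which dual transitions — both
  traits changing in one instant — are disallowed;
* log10 depth evolved by Brownian motion with branch-specific rate scalars
  and optional deterministic per-group trends;
* occurrence tables with planted curation-rule violations, together with a
  matching synthetic bathymetry raster, so that curation recall and
  false-drop rates are computable by construction.

All functions take an integer seed and return byte-identical output for the
same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treekit import TimeTree
from .occurrence_curation import BathymetryGrid

STATES = ("AS", "AC", "ZS", "ZC")
#: state index -> (symbiotic, colonial)
STATE_TRAITS = {0: (False, False), 1: (False, True), 2: (True, False), 3: (True, True)}
#: pairs of states that would require both traits to change at once
DUAL_PAIRS = ((0, 3), (1, 2))


@dataclass
class SimulationConfig:
    """Bundle of generator settings for a full synthetic study."""

    n_tips: int = 500
    birth: float = 0.06          # speciations per lineage per Ma
    death: float = 0.02          # extinctions per lineage per Ma
    sigma2: float = 0.005        # log10-depth variance per Ma
    root_depth_log: float = 3.0  # log10 m (~1000 m, bathyal root)
    seed: int = 0
    scalar_map: dict = field(default_factory=dict)
    trend_beta: dict = field(default_factory=dict)
    Q: np.ndarray | None = None


# ---------------------------------------------------------------------------
# birth–death tree


def simulate_tree(n_tips: int, birth: float, death: float, seed: int) -> TimeTree:
    """Simulate an ultrametric birth–death time tree with ``n_tips`` tips.

    The process starts from a crown split (two lineages), runs until
    ``n_tips`` lineages are simultaneously extant, then extends all pendant
    branches by a fresh waiting-time draw so that no tip branch has zero
    length; extinct lineages are pruned.  If the process dies out it is
    restarted with a fresh stream from the same generator, so output stays a
    deterministic function of the seed.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = np.random.default_rng(seed)
    while True:
        res = _grow(n_tips, birth, death, rng)
        if res is not None:
            return res


def _grow(n_tips, birth, death, rng):
    # node records: parent, birth_time; active nodes are current lineages
    parent = [-1, 0, 0]
    t_birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    total = birth + death
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * total))
        idx = rng.integers(k)
        node = active[idx]
        if rng.random() < birth / total:
            for _ in range(2):
                parent.append(node)
                t_birth.append(t)
            active[idx] = len(parent) - 2
            active.append(len(parent) - 1)
        else:
            active.pop(idx)
            if len(active) < 2:
                return None
    # stop strictly inside the next inter-event interval
    t_end = t + rng.exponential(1.0 / (len(active) * total)) * rng.random()
    return _prune_to_tree(parent, t_birth, active, t_end)


def _prune_to_tree(parent, t_birth, active, t_end):
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    extant = set(active)
    # keep nodes with an extant descendant; iterate reverse creation order
    keep = [False] * n
    for i in range(n - 1, -1, -1):
        keep[i] = i in extant or any(keep[c] for c in children[i])
    # build (label, length, children) recursively with unary suppression
    def build(i, extra):
        kept = [c for c in children[i] if keep[c]]
        end = t_end if i in extant else t_birth[kept[0]]
        length = end - t_birth[i] + extra
        if i in extant:
            return (None, length, [])
        if len(kept) == 1:
            return build(kept[0], length)  # unary node: merge branch lengths
        return (None, length, [build(c, 0.0) for c in kept])

    import sys
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 20 * n + 100))
    root = build(0, 0.0)
    while len(root[2]) == 1:  # root itself may be unary after pruning
        root = root[2][0]

    # flatten post-order
    parent_a: list[int] = []
    length_a: list[float] = []
    labels: list[str | None] = []
    counter = [0]

    def flatten(node):
        _, ln, ch = node
        ids = [flatten(c) for c in ch]
        me = len(parent_a)
        parent_a.append(-1)
        length_a.append(ln)
        if not ch:
            counter[0] += 1
            labels.append(f"t{counter[0]}")
        else:
            labels.append(None)
        for cid in ids:
            parent_a[cid] = me
        return me

    flatten(root)
    length_a[-1] = 0.0  # ignore any root edge
    return TimeTree(parent_a, length_a, labels)


# ---------------------------------------------------------------------------
# correlated discrete traits


def validate_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (4, 4):
        raise ValueError("Q must be 4x4")
    off = Q[~np.eye(4, dtype=bool)]
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-9:
        raise ValueError("rows of Q must sum to 0")
    for a, b in DUAL_PAIRS:
        if Q[a, b] != 0 or Q[b, a] != 0:
            raise ValueError("dual-transition rates must be 0")
    return Q


def simulate_correlated_traits(
    tree: TimeTree, Q: np.ndarray, root_state: int, seed: int
) -> tuple[dict[str, int], np.ndarray]:
    """Evolve the 4-state symbiosis/coloniality chain along the tree.

    Returns ``(tip_states, node_states)``: tip states keyed by label, and
    the full true state per node id (for recovery tests).
    """
    Q = validate_rate_matrix(Q)
    rng = np.random.default_rng(seed)
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[tree.root] = int(root_state)
    for i in tree.preorder():
        p = tree.parent[i]
        if p < 0:
            continue
        s = states[p]
        t_left = tree.length[i]
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait > t_left:
                break
            t_left -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            s = rng.choice(4, p=probs / probs.sum())
        states[i] = s
    tips = {tree.labels[i]: int(states[i]) for i in tree.tip_ids}
    return tips, states


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC rate matrix (left null vector)."""
    w, v = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# rate-heterogeneous Brownian depth


def simulate_depth(
    tree: TimeTree,
    sigma2: float,
    root_depth_log: float,
    seed: int,
    scalar_map: dict[int, float] | None = None,
    trend_beta_by_group: dict | None = None,
    branch_groups: dict[int, object] | None = None,
) -> np.ndarray:
    """Brownian log10 depth with branch rate scalars and per-group drift.

    ``scalar_map`` maps branch id (the node id below the branch) to a rate
    scalar r; the increment on a branch has variance
    ``sigma2 * length * r``.  ``trend_beta_by_group`` adds a deterministic
    drift ``beta * length`` on branches whose ``branch_groups`` label is in
    the map.  Returns the value at every node (tips included), so true
    ancestral values are available to recovery tests.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    scalar_map = scalar_map or {}
    for b in scalar_map:
        if not 0 <= b < tree.n_nodes - 1:
            raise KeyError(f"unknown branch id {b} in scalar_map")
    rng = np.random.default_rng(seed)
    x = np.empty(tree.n_nodes)
    x[tree.root] = root_depth_log
    for i in tree.preorder():
        p = tree.parent[i]
        if p < 0:
            continue
        r = scalar_map.get(int(i), 1.0)
        drift = 0.0
        if trend_beta_by_group and branch_groups is not None:
            g = branch_groups.get(int(i))
            if g in trend_beta_by_group:
                drift = trend_beta_by_group[g] * tree.length[i]
        x[i] = x[p] + drift + rng.normal(0.0, np.sqrt(sigma2 * tree.length[i] * r))
    return x


# ---------------------------------------------------------------------------
# occurrences with planted curation violations


def make_range_table(n_species: int, seed: int, frac_symbiotic: float = 0.6) -> pd.DataFrame:
    """A plausible species range table to drive the occurrence generator.

    Zooxanthellate species get shallow photic boxes (all within 165 m);
    azooxanthellate species get boxes anywhere between 1 and 5600 m.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_species):
        symbiotic = rng.random() < frac_symbiotic
        if symbiotic:
            lo = rng.uniform(1, 60)
            hi = lo + rng.uniform(5, 165 - lo - 1)
        else:
            lo = rng.uniform(1, 3000)
            hi = lo + rng.uniform(50, min(2500, 5600 - lo))
        lat0 = rng.uniform(-35, 25)
        rows.append(
            {
                "species": f"sp{i+1}",
                "depth_min": lo,
                "depth_max": hi,
                "lat_min": lat0,
                "lat_max": lat0 + rng.uniform(2, 15),
                "symbiotic": symbiotic,
                "colonial": bool(rng.random() < 0.5),
            }
        )
    return pd.DataFrame(rows)


def _default_grid() -> BathymetryGrid:
    # 60 one-degree columns, depth increasing eastward 25..5925 m;
    # 100 m per column so any target depth has a matching cell within 75 m.
    ncols, nrows = 60, 80
    col_depth = 25.0 + 100.0 * np.arange(ncols)
    depth = np.tile(col_depth, (nrows, 1))
    return BathymetryGrid(depth, xll=0.0, yll=-40.0, cellsize=1.0)


def simulate_occurrences(
    range_table: pd.DataFrame,
    n_per_species: int,
    planted_violations: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, BathymetryGrid]:
    """Occurrence records uniform in each species' depth/latitude box.

    Clean records are placed in bathymetry cells matching their depth so they
    pass every filter.  ``planted_violations`` maps rule name —
    ``bathymetry_mismatch``, ``photic_gap``, ``az_depth_cap`` — to the number
    of labelled violating records to plant; each planted record violates
    exactly its own rule.  Returns the table (with a ``violation`` column,
    empty string for clean records) and the raster.
    """
    rt = range_table.reset_index(drop=True)
    if np.any(rt["depth_min"] > rt["depth_max"]):
        raise ValueError("invalid range: depth_min > depth_max")
    rng = np.random.default_rng(seed)
    grid = _default_grid()
    planted = dict(planted_violations or {})
    rows = []

    def place(sp, depth, lat, violation="", cell_offset=0):
        col = int(np.clip(round((depth - 25.0) / 100.0), 0, grid.ncols - 1))
        col = int(np.clip(col + cell_offset, 0, grid.ncols - 1))
        lon = grid.xll + (col + rng.uniform(0.2, 0.8)) * grid.cellsize
        rows.append({"species": sp, "lon": lon, "lat": lat,
                     "depth_m": depth, "violation": violation})

    for _, r in rt.iterrows():
        for _ in range(n_per_species):
            depth = rng.uniform(r["depth_min"], r["depth_max"])
            lat = rng.uniform(r["lat_min"], r["lat_max"])
            place(r["species"], depth, lat)

    z_species = rt[rt["symbiotic"]]
    az_species = rt[~rt["symbiotic"]]
    for _ in range(planted.get("bathymetry_mismatch", 0)):
        r = rt.iloc[rng.integers(len(rt))]
        depth = rng.uniform(r["depth_min"], r["depth_max"])
        # 7+ columns away -> grid depth differs by > 600 m
        offset = int(rng.integers(7, 15)) * (1 if depth < 3000 else -1)
        place(r["species"], depth, rng.uniform(r["lat_min"], r["lat_max"]),
              "bathymetry_mismatch", cell_offset=offset)
    for _ in range(planted.get("photic_gap", 0)):
        if len(z_species) == 0:
            raise ValueError("photic_gap violations need a zooxanthellate species")
        r = z_species.iloc[rng.integers(len(z_species))]
        depth = rng.uniform(300, 800)  # >= 135 m beyond any clean photic record
        place(r["species"], depth, rng.uniform(r["lat_min"], r["lat_max"]),
              "photic_gap")
    for _ in range(planted.get("az_depth_cap", 0)):
        if len(az_species) == 0:
            raise ValueError("az_depth_cap violations need an azooxanthellate species")
        r = az_species.iloc[rng.integers(len(az_species))]
        depth = rng.uniform(5750, 5900)
        place(r["species"], depth, rng.uniform(r["lat_min"], r["lat_max"]),
              "az_depth_cap")

    return pd.DataFrame(rows), grid
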