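"""Branch classification by symbiosis/coloniality history.

Given per-node posterior state probabilities, each node is called per trait
(azooxanthellate / zooxanthellate / uncertain; solitary / colonial /
uncertain) by comparing the trait's marginal probability to a support
threshold.  Each branch then gets, per trait, one of four statuses — a
state, a transition (different assigned states at its two ends), or
uncertain (either end uncalled) — giving sixteen raw combinations that are
merged into eight lineage categories:

=============  =========================================================
AS/AC/ZS/ZC    both traits assigned and unchanged along the branch
TransS         symbiosis transition, any coloniality status
TransC         coloniality transition, symbiosis assigned at both ends
UncS           symbiosis uncertain, coloniality colonial or uncertain
UncC           coloniality uncertain, symbiosis assigned
=============  =========================================================

The three remaining raw combinations (transition-transition,
uncertain-solitary, uncertain-transition) essentially never occur and are
excluded with a log entry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORIES = ("AS", "AC", "ZS", "ZC", "TransS", "TransC", "UncS", "UncC")
EXCLUDED = "excluded"

_SYM_STATES = ("azoox", "zoox")
_COL_STATES = ("solitary", "colonial")
TRANSITION = "transition"
UNCERTAIN = "uncertain"


def assign_node_states(node_probs: np.ndarray, threshold: float = 0.7) -> pd.DataFrame:
    """Per-trait node calls from 4-state posteriors.

    ``node_probs`` is (n_nodes, 4) over (AS, AC, ZS, ZC).  A trait is called
    when its marginal probability (summing over the other trait) reaches
    ``threshold``; otherwise it is uncertain.  ``threshold`` must be in
    (0.5, 1] so at most one state can win.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    p = np.asarray(node_probs, dtype=float)
    p_az = p[:, 0] + p[:, 1]
    p_sol = p[:, 0] + p[:, 2]
    sym = np.where(p_az >= threshold, "azoox",
                   np.where(1.0 - p_az >= threshold, "zoox", UNCERTAIN))
    col = np.where(p_sol >= threshold, "solitary",
                   np.where(1.0 - p_sol >= threshold, "colonial", UNCERTAIN))
    return pd.DataFrame({"node_id": np.arange(p.shape[0]),
                         "symbiosis": sym, "coloniality": col})


def _branch_status(parent_call: str, child_call: str) -> str:
    if UNCERTAIN in (parent_call, child_call):
        return UNCERTAIN
    if parent_call == child_call:
        return parent_call
    return TRANSITION


def merge_raw_label(sym_status: str, col_status: str) -> str:
    """Map a raw (symbiosis status, coloniality status) pair to a category.

    Returns ``"excluded"`` for the three combinations dropped from the
    analysis.
    """
    sym_assigned = sym_status in _SYM_STATES
    col_assigned = col_status in _COL_STATES
    if sym_status == TRANSITION:
        return EXCLUDED if col_status == TRANSITION else "TransS"
    if sym_status == UNCERTAIN:
        if col_status in ("colonial", UNCERTAIN):
            return "UncS"
        return EXCLUDED  # uncertain-solitary, uncertain-transition
    # symbiosis assigned
    if col_status == TRANSITION:
        return "TransC"
    if col_status == UNCERTAIN:
        return "UncC"
    assert sym_assigned and col_assigned
    return {"azoox": "A", "zoox": "Z"}[sym_status] + \
           {"solitary": "S", "colonial": "C"}[col_status]


def merge_raw_counts(raw_counts: dict[tuple[str, str], int]) -> dict[str, int]:
    """Aggregate raw 16-way combination counts into the eight categories.

    Keys are (symbiosis status, coloniality status) with statuses in
    {azoox, zoox, transition, uncertain} x {solitary, colonial, transition,
    uncertain}; excluded combinations aggregate under ``"excluded"``.
    """
    out: dict[str, int] = {}
    for (s, c), n in raw_counts.items():
        cat = merge_raw_label(s, c)
        out[cat] = out.get(cat, 0) + n
    return out


def classify_branches(tree, node_calls: pd.DataFrame) -> pd.DataFrame:
    """Category of every branch from the per-trait calls of its two ends.

    Returns one row per branch: ``branch_id, parent, child, raw_sym,
    raw_col, category`` plus a ``transition_direction`` note (e.g.
    ``azoox->zoox``) where a trait transitions.  Branches whose raw
    combination is excluded get category ``"excluded"``.
    """
    calls = node_calls.set_index("node_id")
    rows = []
    for pad in tree.enumerate_pads():
        try:
            pc = calls.loc[pad.ancestor]
            cc = calls.loc[pad.descendant]
        except KeyError as exc:
            raise ValueError(f"missing node call for node {exc.args[0]}") from exc
        s = _branch_status(pc["symbiosis"], cc["symbiosis"])
        c = _branch_status(pc["coloniality"], cc["coloniality"])
        direction = []
        if s == TRANSITION:
            direction.append(f"{pc['symbiosis']}->{cc['symbiosis']}")
        if c == TRANSITION:
            direction.append(f"{pc['coloniality']}->{cc['coloniality']}")
        rows.append({
            "branch_id": pad.branch_id,
            "parent": pad.ancestor,
            "child": pad.descendant,
            "raw_sym": s,
            "raw_col": c,
            "category": merge_raw_label(s, c),
            "transition_direction": ";".join(direction),
        })
    return pd.DataFrame(rows)
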