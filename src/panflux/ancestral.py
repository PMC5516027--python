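"""Ancestral gene-content reconstruction by asymmetric Wagner parsimony.

Family copy numbers are integer characters on a rooted tree. The transition
cost from parent state p to child state c is ``gain_penalty * (c - p)`` for
increases and ``p - c`` for decreases; a family present at the root pays a
root-origination cost of ``gain_penalty * root_state`` (without it, an
all-present family would have degenerate zero cost at any root state). The
dynamic program is the standard Sankoff bottom-up cost table followed by a
top-down traceback. Cost ties are broken toward the largest ancestral count
at every node: at gain penalty 1, "present + one loss below" exactly ties
"absent + two convergent gains", and the single-origin reading (one gain,
later loss) is preferred over convergent gain of the same family. The rule
is deterministic and is what lets per-branch loss events be recovered.

Per-branch changes are classified into four events by comparing each node
with its immediate ancestor: gain (0 -> >=1), loss (>=1 -> 0), expansion
(increase with parent >= 1) and reduction (decrease with child >= 1). A
0 -> c >= 2 branch counts as a single gain; the copy-number jump is kept in a
supplementary column rather than double-counted as gain + expansion.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

DEFAULT_MAX_COUNT = 10

EVENTS = ("gain", "loss", "expansion", "reduction")


def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def ensure_labels(tree: dendropy.Tree) -> None:
    """Assign N1.. labels to unlabelled internal nodes (in preorder)."""
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            k += 1
            node.label = f"anc{k}"


@dataclass
class AncestralStates:
    states: dict[str, dict[str, int]]  # family -> node label -> count
    cost: dict[str, float]  # family -> minimal parsimony cost
    gain_penalty: float = 1.0

    def root_family_count(self, tree: dendropy.Tree) -> int:
        root = _node_label(tree.seed_node)
        return sum(1 for fam in self.states if self.states[fam][root] >= 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states).T.sort_index()


def _transition_cost(p: np.ndarray, c: np.ndarray, gain_penalty: float) -> np.ndarray:
    d = c - p
    return np.where(d > 0, gain_penalty * d, -d).astype(float)


def wagner_parsimony(
    tree: dendropy.Tree,
    profile: dict[str, dict[str, int]],
    gain_penalty: float = 1.0,
    max_count: int | None = None,
) -> AncestralStates:
    """Minimal-cost ancestral counts for every family in ``profile``.

    ``profile`` maps family -> {leaf label -> count}; leaves absent from a
    family's mapping are treated as 0 (with a warning if the leaf never
    appears anywhere). ``max_count`` caps the state space (default: the
    family's maximum observed count, globally capped at 10; higher
    observations are truncated with a warning).
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    ensure_labels(tree)
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    seen = set().union(*(set(v) for v in profile.values())) if profile else set()
    if seen - leaf_labels:
        raise ValueError(f"profile references unknown leaves: {sorted(seen - leaf_labels)[:5]}")
    if leaf_labels - seen and profile:
        warnings.warn(
            f"leaves with no observations treated as 0: {sorted(leaf_labels - seen)[:5]}"
        )

    states: dict[str, dict[str, int]] = {}
    costs: dict[str, float] = {}
    postorder = list(tree.postorder_node_iter())
    for fam, leaf_counts in profile.items():
        obs_max = max(leaf_counts.values(), default=0)
        cap = max_count if max_count is not None else min(obs_max, DEFAULT_MAX_COUNT)
        cap = max(cap, 1)
        if obs_max > cap:
            warnings.warn(f"{fam}: counts above {cap} truncated")
        k = cap + 1
        state_axis = np.arange(k)
        table: dict[int, np.ndarray] = {}
        for node in postorder:
            if node.is_leaf():
                obs = min(leaf_counts.get(node.taxon.label, 0), cap)
                col = np.full(k, np.inf)
                col[obs] = 0.0
                table[id(node)] = col
            else:
                col = np.zeros(k)
                for child in node.child_nodes():
                    child_cost = table[id(child)]
                    # cost matrix over (parent state, child state)
                    tc = _transition_cost(
                        state_axis[:, None], state_axis[None, :], gain_penalty
                    )
                    col += (tc + child_cost[None, :]).min(axis=1)
                table[id(node)] = col
        root = tree.seed_node
        total = table[id(root)] + gain_penalty * state_axis
        # ties -> largest state (single origin + loss beats convergent gains)
        root_state = int(k - 1 - np.argmin(total[::-1]))
        fam_states = {}
        costs[fam] = float(total[root_state])

        def trace(node: dendropy.Node, s: int) -> None:
            fam_states[_node_label(node)] = s
            for child in node.child_nodes():
                child_cost = table[id(child)]
                tc = _transition_cost(np.full(k, s), state_axis, gain_penalty)
                through = tc + child_cost
                child_s = int(k - 1 - np.argmin(through[::-1]))
                trace(child, child_s)

        trace(root, root_state)
        states[fam] = fam_states
    return AncestralStates(states=states, cost=costs, gain_penalty=gain_penalty)


def brute_force_parsimony(
    tree: dendropy.Tree,
    leaf_counts: dict[str, int],
    gain_penalty: float = 1.0,
    max_state: int | None = None,
) -> tuple[float, list[dict[str, int]]]:
    """Exhaustive-enumeration oracle for one family.

    Enumerates every internal-node state assignment over 0..max_state and
    returns (minimal cost, all optimal assignments including leaf states).
    Refuses instances with more than 5 internal nodes or max_state > 4.
    """
    ensure_labels(tree)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    cap = max_state if max_state is not None else max(leaf_counts.values(), default=0)
    cap = max(cap, 1)
    if len(internal) > 5 or cap > 4:
        raise ValueError("instance too large for brute force")
    best_cost = np.inf
    optima: list[dict[str, int]] = []
    for assignment in itertools.product(range(cap + 1), repeat=len(internal)):
        state = {_node_label(n): s for n, s in zip(internal, assignment)}
        for leaf in tree.leaf_node_iter():
            state[leaf.taxon.label] = leaf_counts.get(leaf.taxon.label, 0)
        cost = gain_penalty * state[_node_label(tree.seed_node)]
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            p = state[_node_label(node.parent_node)]
            c = state[_node_label(node)]
            cost += gain_penalty * (c - p) if c > p else p - c
        if cost < best_cost - 1e-12:
            best_cost = cost
            optima = [state]
        elif abs(cost - best_cost) <= 1e-12:
            optima.append(state)
    return float(best_cost), optima


@dataclass
class BranchEventSummary:
    """Per-branch event counts; branches keyed by the child node's label."""

    counts: pd.DataFrame  # index = branch (child label); columns G, L, E, R
    per_family: pd.DataFrame = field(default_factory=pd.DataFrame)

    def annotate_newick(self, tree: dendropy.Tree) -> str:
        """Newick with G/L/E/R comment blocks on each branch."""
        ensure_labels(tree)
        clone = tree.clone(depth=1)
        for node in clone.preorder_node_iter():
            if node.parent_node is None:
                continue
            label = _node_label(node)
            if label in self.counts.index:
                row = self.counts.loc[label]
                note = f"G{int(row.G)}/L{int(row.L)}/E{int(row.E)}/R{int(row.R)}"
                node.edge.annotations.add_new("events", note)
        return clone.as_string(schema="newick", suppress_annotations=False).strip()


def classify_events(states: AncestralStates, tree: dendropy.Tree) -> BranchEventSummary:
    """Classify per-branch, per-family changes into G/L/E/R.

    Each (family, branch) contributes at most one event. The ``delta`` column
    of the per-family table records the signed copy-number change, so a
    0 -> 3 gain keeps its magnitude without being counted as an expansion.
    """
    ensure_labels(tree)
    branches = [
        _node_label(n) for n in tree.preorder_node_iter() if n.parent_node is not None
    ]
    counts = pd.DataFrame(0, index=branches, columns=list("GLER"))
    rows = []
    for fam, node_states in states.states.items():
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            p = node_states[_node_label(node.parent_node)]
            c = node_states[_node_label(node)]
            if p == c:
                continue
            if p == 0 and c >= 1:
                ev = "G"
            elif p >= 1 and c == 0:
                ev = "L"
            elif c > p >= 1:
                ev = "E"
            else:  # p > c >= 1
                ev = "R"
            branch = _node_label(node)
            counts.loc[branch, ev] += 1
            rows.append({"branch": branch, "family": fam, "event": ev, "delta": c - p})
    per_family = pd.DataFrame(rows, columns=["branch", "family", "event", "delta"])
    return BranchEventSummary(counts=counts, per_family=per_family)
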