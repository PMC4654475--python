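"""Gain/loss inference of piC expression on a dated phylogeny.

Binary presence/absence characters are reconstructed by Wagner
parsimony (Sankoff dynamic programming with gain and loss costs,
default 1:1).  Root-state ties are broken toward absence, matching the
inference that ancestral repertoires were small; internal ties prefer
the parent state (no event) and then absence.  Events are summed per
branch and divided by branch lengths (million years) to give
per-branch gain and loss rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

_INF = np.inf


def _branch_id(node: dendropy.Node, index: int) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{index}"


@dataclass
class ParsimonyResult:
    total_cost: float
    #: per-character ancestral state at each node id
    states: dict[str, np.ndarray] = field(default_factory=dict)
    #: per-branch (child node id) -> (gains, losses) summed over characters
    branch_events: dict[str, tuple[int, int]] = field(default_factory=dict)
    branch_lengths: dict[str, float] = field(default_factory=dict)
    #: branch id -> leaf labels below it (topology-stable identifier)
    branch_leafsets: dict[str, frozenset[str]] = field(default_factory=dict)
    character_ids: list[str] = field(default_factory=list)
    #: per-character per-branch events: branch id -> (gain mask, loss mask)
    branch_event_masks: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @property
    def total_gains(self) -> int:
        return sum(g for g, _ in self.branch_events.values())

    @property
    def total_losses(self) -> int:
        return sum(l for _, l in self.branch_events.values())


def wagner_parsimony(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
    root_prior: str = "absent",
) -> ParsimonyResult:
    """Minimum-cost ancestral reconstruction of binary characters.

    ``matrix`` is loci x taxa with entries in {0, 1}; taxa must match
    the tree leaves exactly.  Costs: 0->1 transition = gain_cost,
    1->0 = loss_cost.  All characters are processed vectorized.
    """
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    taxa = set(matrix.columns)
    if leaf_names != taxa:
        raise ValueError(
            f"taxa mismatch: tree has {sorted(leaf_names)}, matrix has {sorted(taxa)}"
        )
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("presence matrix entries must be 0 or 1")
    if root_prior not in ("absent", "present", "min"):
        raise ValueError("root_prior must be 'absent', 'present' or 'min'")
    n_chars = matrix.shape[0]

    # transition cost matrix: trans[s, t] = cost of parent state s -> child t
    trans = np.array([[0.0, gain_cost], [loss_cost, 0.0]])

    nodes = list(tree.postorder_node_iter())
    node_index = {id(n): i for i, n in enumerate(nodes)}
    ids = {id(n): _branch_id(n, i) for i, n in enumerate(nodes)}

    # Sankoff bottom-up: cost[node] has shape (n_chars, 2)
    cost: dict[int, np.ndarray] = {}
    for node in nodes:
        if node.is_leaf():
            obs = matrix[node.taxon.label].to_numpy().astype(int)
            c = np.full((n_chars, 2), _INF)
            c[np.arange(n_chars), obs] = 0.0
        else:
            c = np.zeros((n_chars, 2))
            for child in node.child_nodes():
                cc = cost[id(child)]
                # best[s] = min_t (cc[:, t] + trans[s, t])
                for s in (0, 1):
                    c[:, s] += np.minimum(cc[:, 0] + trans[s, 0],
                                          cc[:, 1] + trans[s, 1])
        cost[id(node)] = c

    root = tree.seed_node
    root_cost = cost[id(root)]
    total_cost = float(np.minimum(root_cost[:, 0], root_cost[:, 1]).sum())

    # top-down state choice
    states: dict[str, np.ndarray] = {}
    chosen: dict[int, np.ndarray] = {}
    if root_prior == "present":
        root_state = np.where(root_cost[:, 1] <= root_cost[:, 0], 1, 0)
    else:  # 'absent' and 'min' both break exact ties toward 0
        root_state = np.where(root_cost[:, 1] < root_cost[:, 0], 1, 0)
    chosen[id(root)] = root_state
    states[ids[id(root)]] = root_state

    leafsets: dict[int, frozenset[str]] = {}
    for node in nodes:  # postorder: children first
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            leafsets[id(node)] = frozenset().union(
                *(leafsets[id(c)] for c in node.child_nodes())
            )

    branch_events: dict[str, tuple[int, int]] = {}
    branch_lengths: dict[str, float] = {}
    branch_leafsets: dict[str, frozenset[str]] = {}
    branch_event_masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = chosen[id(node.parent_node)]
        c = cost[id(node)]
        cost_if_0 = c[:, 0] + trans[parent_state, 0]
        cost_if_1 = c[:, 1] + trans[parent_state, 1]
        # prefer the cheaper state; on ties keep the parent state, then 0
        state = np.where(
            cost_if_1 < cost_if_0, 1,
            np.where(cost_if_0 < cost_if_1, 0, np.where(parent_state == 1, 1, 0)),
        )
        chosen[id(node)] = state
        nid = ids[id(node)]
        states[nid] = state
        gain_mask = (parent_state == 0) & (state == 1)
        loss_mask = (parent_state == 1) & (state == 0)
        branch_events[nid] = (int(gain_mask.sum()), int(loss_mask.sum()))
        branch_event_masks[nid] = (gain_mask, loss_mask)
        branch_lengths[nid] = float(node.edge.length or 0.0)
        branch_leafsets[nid] = leafsets[id(node)]

    return ParsimonyResult(
        total_cost=total_cost,
        states=states,
        branch_events=branch_events,
        branch_lengths=branch_lengths,
        branch_leafsets=branch_leafsets,
        character_ids=[str(i) for i in matrix.index],
        branch_event_masks=branch_event_masks,
    )


def branch_rates(result: ParsimonyResult, n_characters: int | None = None) -> pd.DataFrame:
    """Per-branch gains, losses and rates (events per MY).

    Rates on zero-length branches are NaN and flagged.  When
    ``n_characters`` is given, per-character rates are reported too.
    """
    rows = []
    for branch, (gains, losses) in sorted(result.branch_events.items()):
        length = result.branch_lengths[branch]
        defined = length > 0
        row = {
            "branch": branch,
            "gains": gains,
            "losses": losses,
            "length_my": length,
            "gain_rate": gains / length if defined else np.nan,
            "loss_rate": losses / length if defined else np.nan,
            "rate_defined": defined,
        }
        if n_characters:
            row["gain_rate_per_locus"] = (
                gains / length / n_characters if defined else np.nan
            )
            row["loss_rate_per_locus"] = (
                losses / length / n_characters if defined else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def presence_matrix(table: pd.DataFrame, min_rpm: float = 10.0) -> pd.DataFrame:
    """Binarize a repertoire table: 1 where RPM >= min_rpm, else 0."""
    return (table.fillna(-np.inf) >= min_rpm).astype(int)
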