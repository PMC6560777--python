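"""Per-branch gene-family gain/loss reconstruction on a dated tree.

Ancestral states are reconstructed by Wagner parsimony via the Sankoff
dynamic program: in presence mode the character is 0/1 with unit cost per
change; in count mode states run 0..max observed count with cost |i - j|.
Ties are broken by preferring the smaller state at every node, which is
deterministic and places gains as late (towards the leaves) as possible.
An alternative Dollo reconstruction forces a single origin per family
(gain at the MRCA of possessing leaves) with minimally placed losses,
appropriate for characters such as orphan families that are unlikely to
arise twice.

This is a deliberate parsimony-based treatment of family-size evolution;
no birth-death rate estimation or family-level significance testing is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ClusterTable, TimeTree

RATE_UNDEFINED = float("nan")


@dataclass
class GainLossMap:
    """Reconstructed states and per-branch change counts.

    ``node_states[name]`` is the state vector (one entry per cluster) at
    the named node; ``branches`` has one row per non-root edge with
    cluster-level gain/loss counts and gene-level sums (equal to the
    cluster-level counts in presence mode).
    """

    mode: str
    cluster_ids: list[str]
    node_states: dict[str, np.ndarray]
    branches: pd.DataFrame
    total_cost: int
    per_cluster_cost: np.ndarray = field(default=None)


def _check_leaves(table: ClusterTable, tree: TimeTree) -> None:
    leaves = set(tree.leaf_labels)
    taxa = set(table.taxa)
    if leaves != taxa:
        only_tree = sorted(leaves - taxa)
        only_table = sorted(taxa - leaves)
        raise ValueError(
            f"tree leaves and table taxa differ: only in tree {only_tree}, "
            f"only in table {only_table}"
        )


def wagner_parsimony(
    table: ClusterTable, tree: TimeTree, mode: str = "presence"
) -> GainLossMap:
    """Sankoff dynamic-programming reconstruction of ancestral family states.

    ``mode='presence'`` uses 0/1 states with unit change cost;
    ``mode='count'`` uses integer states 0..max observed with cost |i-j|.
    The minimal total cost is exact; among minimal reconstructions, the
    smallest state is preferred at the root and at every child given its
    parent (deterministic tie-break).
    """
    if mode not in ("presence", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_leaves(table, tree)
    nclus = table.n_clusters
    if mode == "presence":
        obs = table.presence().astype(np.int64)
        n_states = 2
    else:
        obs = table.counts
        n_states = int(obs.max()) + 1 if nclus else 1
    tix = {t: i for i, t in enumerate(table.taxa)}

    INF = np.iinfo(np.int64).max // 4
    cost: dict[int, np.ndarray] = {}  # node id -> (n_states, n_clusters)
    nodes_post = list(tree.tree.postorder_node_iter())
    for node in nodes_post:
        if node.is_leaf():
            c = np.full((n_states, nclus), INF, dtype=np.int64)
            states = obs[tix[node.taxon.label]]
            c[states, np.arange(nclus)] = 0
        else:
            c = np.zeros((n_states, nclus), dtype=np.int64)
            for child in node.child_nodes():
                cc = cost[id(child)]
                # min over child state t of cc[t] + |s - t|, for each s
                best = np.full((n_states, nclus), INF, dtype=np.int64)
                for s in range(n_states):
                    trans = np.abs(s - np.arange(n_states))[:, None]
                    best[s] = (cc + trans).min(axis=0)
                c = c + best
        cost[id(node)] = c

    root = tree.root
    root_cost = cost[id(root)]
    per_cluster_cost = root_cost.min(axis=0)
    # smallest state among minimal-cost root states
    root_state = np.argmax(root_cost == per_cluster_cost[None, :], axis=0)

    node_states: dict[str, np.ndarray] = {}
    assigned: dict[int, np.ndarray] = {id(root): root_state}
    node_states[tree.node_name(root)] = root_state
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assigned[id(node.parent_node)]
        cc = cost[id(node)]
        # child state = smallest t minimizing cc[t] + |t - parent|
        totals = cc + np.abs(
            np.arange(n_states)[:, None] - parent_state[None, :]
        )
        best = totals.min(axis=0)
        state = np.argmax(totals == best[None, :], axis=0)
        assigned[id(node)] = state
        node_states[tree.node_name(node)] = state

    rows = []
    for parent, child, length in tree.edges():
        ps = assigned[id(parent)]
        cs = assigned[id(child)]
        diff = cs.astype(np.int64) - ps.astype(np.int64)
        rows.append(
            {
                "parent": tree.node_name(parent),
                "child": tree.node_name(child),
                "length_mya": length,
                "n_gains": int((diff > 0).sum()),
                "n_losses": int((diff < 0).sum()),
                "gene_gains": int(diff[diff > 0].sum()),
                "gene_losses": int(-diff[diff < 0].sum()),
            }
        )
    return GainLossMap(
        mode=mode,
        cluster_ids=list(table.cluster_ids),
        node_states=node_states,
        branches=pd.DataFrame(rows),
        total_cost=int(per_cluster_cost.sum()),
        per_cluster_cost=per_cluster_cost,
    )


def dollo_parsimony(table: ClusterTable, tree: TimeTree) -> GainLossMap:
    """Single-origin reconstruction: each family is gained exactly once at
    the MRCA of the taxa possessing it and lost minimally afterwards
    (one loss per maximal possession-free subtree under the MRCA)."""
    _check_leaves(table, tree)
    pres = table.presence()
    tix = {t: i for i, t in enumerate(table.taxa)}
    nclus = table.n_clusters

    # per node: set of descendant leaf indices
    desc: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            mask = np.zeros(len(table.taxa), dtype=bool)
            mask[tix[node.taxon.label]] = True
        else:
            mask = np.zeros(len(table.taxa), dtype=bool)
            for child in node.child_nodes():
                mask |= desc[id(child)]
        desc[id(node)] = mask

    node_list = list(tree.tree.preorder_node_iter())
    states = {id(n): np.zeros(nclus, dtype=np.int64) for n in node_list}
    gains = {id(n): np.zeros(nclus, dtype=bool) for n in node_list}
    losses = {id(n): np.zeros(nclus, dtype=bool) for n in node_list}
    total_cost = np.zeros(nclus, dtype=np.int64)

    for j in range(nclus):
        have = pres[:, j]
        if not have.any():
            continue
        # MRCA = deepest node whose descendant set covers all possessors
        mrca = tree.root
        changed = True
        while changed:
            changed = False
            for child in mrca.child_nodes():
                if (have & ~desc[id(child)]).sum() == 0:
                    mrca = child
                    changed = True
                    break
        gains[id(mrca)][j] = True
        total_cost[j] += 1
        # mark presence on paths, losses at stems of possession-free subtrees
        stack = [mrca]
        while stack:
            node = stack.pop()
            if (have & desc[id(node)]).any():
                states[id(node)][j] = 1
                stack.extend(node.child_nodes())
            else:
                losses[id(node)][j] = True
                total_cost[j] += 1

    node_states = {tree.node_name(n): states[id(n)] for n in node_list}
    rows = []
    for parent, child, length in tree.edges():
        g = gains[id(child)]
        l = losses[id(child)]
        rows.append(
            {
                "parent": tree.node_name(parent),
                "child": tree.node_name(child),
                "length_mya": length,
                "n_gains": int(g.sum()),
                "n_losses": int(l.sum()),
                "gene_gains": int(g.sum()),
                "gene_losses": int(l.sum()),
            }
        )
    return GainLossMap(
        mode="dollo",
        cluster_ids=list(table.cluster_ids),
        node_states=node_states,
        branches=pd.DataFrame(rows),
        total_cost=int(total_cost.sum()),
        per_cluster_cost=total_cost,
    )


def branch_rates(glmap: GainLossMap, tree: TimeTree | None = None) -> pd.DataFrame:
    """Per-branch change rate: (cluster gains + losses) / branch length Mya.

    Zero-length branches get NaN (undefined), never infinity.  The root
    itself has no branch and does not appear.
    """
    df = glmap.branches.copy()
    changes = df["n_gains"] + df["n_losses"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(df["length_mya"] > 0, changes / df["length_mya"], RATE_UNDEFINED)
    df["rate_per_mya"] = rate
    return df
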