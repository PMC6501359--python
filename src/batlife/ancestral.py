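"""Squared-change parsimony ancestral reconstruction and origin counting.

Given observed trait values at the tips, squared-change parsimony assigns
values to internal nodes minimizing the sum over edges of squared changes,
optionally weighted by inverse branch length:

    S = sum_e (x_parent(e) - x_child(e))^2 / len(e)        (weighted)
    S = sum_e (x_parent(e) - x_child(e))^2                 (unweighted)

The objective is a strictly convex quadratic in the internal-node values, so
the minimum is unique and found by one sparse linear solve of the normal
equations. The branch-length-weighted solution coincides with the joint
maximum-likelihood ancestral states under Brownian motion.

Origins of "extreme" trait values are counted as threshold crossings on
edges: a node whose reconstructed (or observed) value exceeds the threshold
while its parent's does not roots one independent origin; a root above the
threshold roots one as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .trees import Phylogeny

__all__ = ["AncestralReconstruction", "scp_reconstruct", "count_extreme_origins"]


@dataclass
class AncestralReconstruction:
    node_values: dict                      # node label -> value (tips + internal)
    total_weighted_squared_change: float
    weighted: bool
    tree: Phylogeny

    @property
    def ancestral_state(self) -> float:
        """Reconstructed value at the root."""
        return self.node_values[self.tree.labels[self.tree.root]]

    def to_frame(self) -> pd.DataFrame:
        """Node table: node id, parent id, branch length, value."""
        t = self.tree
        rows = []
        for i in range(t.n_nodes):
            p = t.parent[i]
            rows.append({
                "node": t.labels[i],
                "parent": t.labels[p] if p >= 0 else "",
                "branch_length": float(t.length[i]) if p >= 0 else np.nan,
                "is_tip": bool(t.is_tip[i]),
                "value": self.node_values[t.labels[i]],
            })
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        return self.tree.to_newick(node_values=self.node_values)


def scp_reconstruct(tree: Phylogeny, tip_values, weighted: bool = True) -> AncestralReconstruction:
    """Minimize total (weighted) squared change over internal-node values.

    ``tip_values`` maps tip label -> finite value; every tip must be present.
    Weighted mode requires strictly positive branch lengths (apply the
    zero-length epsilon policy first if needed).
    """
    tip_values = {k: float(v) for k, v in tip_values.items()}
    missing = [t for t in tree.tip_labels if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for {missing}")
    bad = [t for t in tree.tip_labels if not np.isfinite(tip_values[t])]
    if bad:
        raise ValueError(f"non-finite tip values for {bad}")

    n = tree.n_nodes
    internal = np.flatnonzero(~tree.is_tip)
    rank = {int(i): r for r, i in enumerate(internal)}
    m = len(internal)
    x = np.zeros(n)
    for i in tree.tip_indices:
        x[i] = tip_values[tree.labels[i]]

    w = np.zeros(n)  # edge weight for the edge above each node
    for i in range(n):
        if tree.parent[i] < 0:
            continue
        if weighted:
            if tree.length[i] <= 0:
                raise ValueError(
                    "weighted reconstruction requires positive branch lengths; "
                    "use Phylogeny.with_min_terminal_length or weighted=False"
                )
            w[i] = 1.0 / tree.length[i]
        else:
            w[i] = 1.0

    # normal equations: for each internal node u,
    #   (sum of weights of incident edges) x_u - sum w_e x_neighbor = 0
    A = sp.lil_matrix((m, m))
    b = np.zeros(m)
    for i in range(n):
        p = tree.parent[i]
        if p < 0:
            continue
        we = w[i]
        i_int, p_int = not tree.is_tip[i], not tree.is_tip[p]
        if i_int:
            A[rank[int(i)], rank[int(i)]] += we
        if p_int:
            A[rank[int(p)], rank[int(p)]] += we
        if i_int and p_int:
            A[rank[int(i)], rank[int(p)]] -= we
            A[rank[int(p)], rank[int(i)]] -= we
        elif i_int:
            b[rank[int(i)]] += we * x[p]
        elif p_int:
            b[rank[int(p)]] += we * x[i]
        # tip-tip edges impossible: a tip is never a parent
    sol = spla.spsolve(A.tocsc(), b) if m else np.array([])
    x[internal] = sol

    total = 0.0
    for i in range(n):
        if tree.parent[i] >= 0:
            total += w[i] * (x[tree.parent[i]] - x[i]) ** 2

    values = {tree.labels[i]: float(x[i]) for i in range(n)}
    return AncestralReconstruction(node_values=values,
                                   total_weighted_squared_change=float(total),
                                   weighted=weighted, tree=tree)


def count_extreme_origins(recon: AncestralReconstruction, threshold: float):
    """Count maximal subtrees whose values cross the threshold upward.

    An origin is an edge where the child's value exceeds the threshold and
    the parent's does not (the root counts if it is itself above). Returns
    ``(count, roots)`` where ``roots`` are the subtree-root node labels in
    the tree's node order.
    """
    t = recon.tree
    vals = np.array([recon.node_values[t.labels[i]] for i in range(t.n_nodes)])
    above = vals > threshold
    roots = []
    for i in range(t.n_nodes):
        p = t.parent[i]
        if above[i] and (p < 0 or not above[p]):
            roots.append(t.labels[i])
    return len(roots), roots
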