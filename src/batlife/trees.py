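"""Phylogeny handling: newick I/O, trait-table alignment, and the
lambda-scaled Brownian covariance matrix used by every downstream stage.

The central object is :class:`Phylogeny`, a lightweight array-backed view of
a rooted tree with branch lengths. The covariance matrix ``C`` has entries
``C[i, j]`` equal to the shared root-to-MRCA path length of tips *i* and *j*
(diagonal = root-to-tip depth); Pagel's lambda multiplies the off-diagonal
entries only, interpolating between a star phylogeny (lambda = 0) and pure
Brownian covariance (lambda = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "TreeError",
    "AlignmentError",
    "read_tree",
    "align",
    "covariance",
    "lambda_transform",
    "normalize_species_name",
]


class TreeError(ValueError):
    """Raised for trees that violate the structural contract."""


class AlignmentError(ValueError):
    """Raised when a tree and trait table cannot be aligned."""


def normalize_species_name(name: str) -> str:
    """Canonical species label: trimmed, internal spaces -> underscores."""
    return "_".join(str(name).strip().split())


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, stored as parallel node arrays.

    Nodes are indexed in a fixed postorder; tips come with their labels,
    internal nodes get deterministic ids ``node<k>`` (postorder rank). The
    root's own edge length is ignored.
    """

    parent: np.ndarray          # parent index per node; -1 at the root
    length: np.ndarray          # branch length of the edge above each node
    labels: list                # per-node label (tip name or node id)
    is_tip: np.ndarray          # boolean per node
    postorder: np.ndarray = field(repr=False)  # node indices, children first

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n, dtype=float)
        is_tip = np.zeros(n, dtype=bool)
        labels: list = [None] * n
        n_internal = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeError("newick tree has an edge without a branch length")
                length[i] = float(nd.edge.length)
                if length[i] < 0:
                    raise TreeError(f"negative branch length {length[i]!r}")
            if nd.is_leaf():
                is_tip[i] = True
                if nd.taxon is None or not str(nd.taxon.label).strip():
                    raise TreeError("tip without a label")
                labels[i] = normalize_species_name(nd.taxon.label)
            else:
                labels[i] = f"node{n_internal}"
                n_internal += 1
        tips = [labels[i] for i in range(n) if is_tip[i]]
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        phy = cls(parent=parent, length=length, labels=labels, is_tip=is_tip,
                  postorder=np.arange(n, dtype=np.int64))
        n_zero = int(np.sum((length[parent >= 0] == 0)))
        if n_zero:
            logger.info("tree has %d zero-length edges", n_zero)
        return phy

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                rooting="default-rooted", suppress_internal_node_taxa=True,
            )
        except Exception as e:
            raise TreeError(f"newick parse error: {e}") from e
        if not tree.is_rooted:
            raise TreeError("tree is explicitly unrooted ([&U]); a rooted tree is required")
        return cls.from_dendropy(tree)

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def children(self) -> list:
        kids: list = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def n_zero_length_edges(self) -> int:
        mask = self.parent >= 0
        return int(np.sum(self.length[mask] == 0))

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        # parents precede children in reverse postorder
        for i in self.postorder[::-1]:
            p = self.parent[i]
            if p >= 0:
                d[i] = d[p] + self.length[i]
        return d

    def tree_depth(self) -> float:
        return float(self.depths()[self.tip_indices].max())

    # -- covariance -------------------------------------------------------

    def shared_path_matrix(self) -> tuple:
        """Raw Brownian covariance: C[i, j] = depth of MRCA(i, j).

        Returns ``(C, tip_labels)`` with rows/columns in tip order.
        """
        depth = self.depths()
        tips = self.tip_indices
        tip_rank = {int(t): r for r, t in enumerate(tips)}
        n = len(tips)
        C = np.zeros((n, n))
        below: list = [None] * self.n_nodes
        for i in self.postorder:
            if self.is_tip[i]:
                below[i] = [tip_rank[int(i)]]
                C[tip_rank[int(i)], tip_rank[int(i)]] = depth[i]
            else:
                groups = [below[c] for c in np.flatnonzero(self.parent == i)]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        for u in groups[a]:
                            for v in groups[b]:
                                C[u, v] = C[v, u] = depth[i]
                merged: list = []
                for g in groups:
                    merged.extend(g)
                below[i] = merged
        return C, self.tip_labels

    def with_min_terminal_length(self, epsilon: float | None = None) -> "Phylogeny":
        """Return a copy whose zero-length terminal edges get ``epsilon``.

        Default epsilon is ``1e-8 x tree depth``; applied edges are logged.
        """
        if epsilon is None:
            epsilon = 1e-8 * self.tree_depth()
        length = self.length.copy()
        mask = self.is_tip & (self.parent >= 0) & (self.length == 0)
        if mask.any():
            logger.info("adding epsilon %.3g to %d zero-length terminal edges",
                        epsilon, int(mask.sum()))
            length[mask] = epsilon
        return Phylogeny(parent=self.parent.copy(), length=length,
                         labels=list(self.labels), is_tip=self.is_tip.copy(),
                         postorder=self.postorder.copy())

    # -- pruning ----------------------------------------------------------

    def prune_to(self, keep_labels) -> "Phylogeny":
        """Prune to the given tip labels, suppressing unifurcations."""
        keep = {normalize_species_name(x) for x in keep_labels}
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise TreeError("cannot prune to fewer than 2 tips")
        tree = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True, rooting="default-rooted")
        tree.retain_taxa_with_labels(sorted(keep))
        # collapse a unifurcating root left behind by pruning
        seed = tree.seed_node
        while len(seed.child_nodes()) == 1:
            child = seed.child_nodes()[0]
            child.edge.length = None
            tree.seed_node = child
            child.parent_node = None
            seed = child
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = 0.0
        return Phylogeny.from_dendropy(tree)

    # -- output -----------------------------------------------------------

    def to_newick(self, node_values: dict | None = None, ndigits: int = 10) -> str:
        """Serialize to newick; optional per-node values become comments."""
        kids = self.children()

        def fmt(i: int) -> str:
            if self.is_tip[i]:
                s = self.labels[i]
            else:
                s = "(" + ",".join(fmt(c) for c in kids[i]) + ")"
            if node_values is not None and self.labels[i] in node_values:
                s += f"[&value={node_values[self.labels[i]]:.{ndigits}g}]"
            if self.parent[i] >= 0:
                s += f":{self.length[i]:.{ndigits}g}"
            return s

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return fmt(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)


def read_tree(path) -> Phylogeny:
    """Read a single rooted newick tree (with branch lengths) from a file."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    phy = Phylogeny.from_newick(text)
    logger.info("read tree with %d tips (%d zero-length edges)",
                phy.n_tips, phy.n_zero_length_edges())
    return phy


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal entries of a covariance matrix by lambda."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def covariance(tree: Phylogeny, lam: float = 1.0, check_pd: bool = False):
    """Lambda-scaled phylogenetic covariance matrix and its tip order.

    ``lam = 1`` reproduces the raw shared-path matrix; ``lam = 0`` is
    diagonal (phylogenetic independence). With ``check_pd`` the matrix is
    required to admit a Cholesky factorization.
    """
    if not np.all(np.isfinite(tree.length)):
        raise TreeError("non-finite branch length")
    C, order = tree.shared_path_matrix()
    C = lambda_transform(C, lam)
    if check_pd:
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            bad = _offending_pair(C, order)
            raise TreeError(
                f"covariance matrix not positive definite (lambda={lam}); "
                f"near-duplicate tips {bad} — consider the zero-length epsilon policy"
            ) from None
    return C, order


def _offending_pair(C: np.ndarray, order: list) -> tuple:
    d = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
    return order[i], order[j]


# -- trait tables ---------------------------------------------------------

#: trait-table columns whose log10 transform the analysis uses
LOG10_COLUMNS = {
    "longevity_years": "log10_longevity",
    "body_mass_g": "log10_mass",
    "aggregation_size": "log10_aggregation",
}


def add_log_columns(traits: pd.DataFrame) -> pd.DataFrame:
    """Append the log10 columns derived from the raw trait columns."""
    out = traits.copy()
    for raw, log in LOG10_COLUMNS.items():
        if raw in out.columns:
            vals = np.asarray(out[raw], dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError(f"column {raw!r} must be positive to take log10")
            out[log] = np.log10(vals)
    return out


def read_traits(path) -> pd.DataFrame:
    """Read a species trait CSV (UTF-8, `species` column required)."""
    df = pd.read_csv(path, encoding="utf-8")
    if "species" not in df.columns:
        raise ValueError("trait table must have a `species` column")
    df["species"] = df["species"].map(normalize_species_name)
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"].unique())
        raise ValueError(f"duplicate species rows: {dupes}")
    return df


def align(tree: Phylogeny, traits: pd.DataFrame, variables: list,
          min_species: int = 3, prune_log: list | None = None):
    """Intersect tree tips with complete-case trait rows for ``variables``.

    Returns ``(pruned_tree, aligned_table)`` with the table's row order equal
    to the pruned tree's tip order. Dropped species are logged (and appended
    to ``prune_log`` if given) with the reason.
    """
    traits = traits.copy()
    traits["species"] = traits["species"].map(normalize_species_name)
    missing_cols = [v for v in variables if v not in traits.columns]
    if missing_cols:
        raise AlignmentError(f"trait table lacks columns {missing_cols}")
    tips = set(tree.tip_labels)
    dropped = []
    keep = []
    for _, row in traits.iterrows():
        sp = row["species"]
        if sp not in tips:
            dropped.append((sp, "missing from tree"))
            continue
        vals = row[variables]
        if vals.isna().any() or not np.all(np.isfinite(np.asarray(vals, dtype=float))):
            bad = [v for v in variables if pd.isna(row[v]) or not np.isfinite(float(row[v]))]
            dropped.append((sp, f"missing value for {','.join(bad)}"))
            continue
        keep.append(sp)
    for sp in sorted(tips - set(traits["species"])):
        dropped.append((sp, "missing from trait table"))
    for sp, why in dropped:
        logger.info("dropped %s: %s", sp, why)
        if prune_log is not None:
            prune_log.append((sp, why))
    if len(keep) < min_species:
        raise AlignmentError(
            f"only {len(keep)} complete cases for {variables}; need >= {min_species}"
        )
    pruned = tree.prune_to(keep)
    table = traits.set_index("species").loc[pruned.tip_labels].reset_index()
    return pruned, table
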