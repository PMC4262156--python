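"""Rooted time trees: node ages in Ma before present, fixed bifurcating topology.

The package works with chronograms whose tips are extant taxa (age 0) and
whose internal nodes carry ages in millions of years before present.  Branch
lengths are derived quantities, ``age(parent) - age(child)``; the primary
objects are the node ages themselves, because calibration priors are priors
on node ages.

Newick parsing and writing go through dendropy; the in-memory representation
is a flat array structure tuned for the MCMC samplers elsewhere in the
package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "TreeFormatError",
    "parse_newick",
    "validate_order",
    "OrderViolation",
]

#: tolerance (Ma) below which tip-age mismatches are treated as rounding noise
ULTRAMETRIC_TOL = 1e-6
#: strict parent-older-than-child tolerance (Ma)
ORDER_TOL = 1e-9


class TreeFormatError(ValueError):
    """Raised for non-ultrametric, non-bifurcating or otherwise invalid input."""


@dataclass(frozen=True)
class OrderViolation:
    """A parent/child pair whose ages violate ancestor-older-than-descendant."""

    parent: str
    child: str
    parent_age: float
    child_age: float


class TimeTree:
    """A rooted bifurcating chronogram over named extant tips.

    Nodes are addressed by integer index: tips first (in Newick order),
    internal nodes in postorder after them; the root is always the last
    index.  Topology is fixed after construction; ages may be replaced
    wholesale via :meth:`with_ages` (returning a shallow copy sharing
    topology), which is what the samplers use.
    """

    def __init__(
        self,
        tip_names: list[str],
        parent: np.ndarray,
        children: list[tuple[int, ...]],
        ages: np.ndarray,
        labels: list[str | None],
    ):
        self.tip_names = list(tip_names)
        self.n_tips = len(tip_names)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.n_nodes = len(self.parent)
        self.children = [tuple(c) for c in children]
        self.ages = np.asarray(ages, dtype=np.float64)
        self.labels = list(labels)
        self.root = int(np.flatnonzero(self.parent == -1)[0])
        self._tip_index = {name: i for i, name in enumerate(tip_names)}
        if len(self._tip_index) != self.n_tips:
            raise TreeFormatError("duplicate tip names")
        self._label_index = {
            lab: i for i, lab in enumerate(self.labels) if lab is not None
        }

    # -- structure ---------------------------------------------------------

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    @property
    def internal_nodes(self) -> list[int]:
        """Internal node indices in postorder (root last)."""
        return list(range(self.n_tips, self.n_nodes))

    def preorder_internal(self) -> list[int]:
        """Internal node indices root-first (each parent before its children)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            if not self.is_tip(v):
                order.append(v)
                stack.extend(self.children[v])
        return order

    def clade_tips(self, node: int) -> frozenset[str]:
        """Names of all tips descended from ``node`` (itself, if a tip)."""
        out: list[str] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(self.tip_names[v])
            else:
                stack.extend(self.children[v])
        return frozenset(out)

    def node_by_label(self, label: str) -> int:
        try:
            return self._label_index[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r}") from None

    def node_name(self, node: int) -> str:
        if self.is_tip(node):
            return self.tip_names[node]
        if self.labels[node] is not None:
            return self.labels[node]
        return f"n{node}"

    def mrca(self, taxa) -> int:
        """Most recent common ancestor of a non-empty set of tip names."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("mrca of an empty taxon set")
        try:
            nodes = [self._tip_index[t] for t in taxa]
        except KeyError as e:
            raise KeyError(f"unknown tip name {e.args[0]!r}") from None
        # ordered tip-to-root path of the first tip; successively truncate it
        anc = nodes[0]
        path: list[int] = []
        v = anc
        while v != -1:
            path.append(v)
            v = int(self.parent[v])
        on_path = {u: i for i, u in enumerate(path)}
        lo = 0
        for t in nodes[1:]:
            v = t
            while v not in on_path:
                v = int(self.parent[v])
            lo = max(lo, on_path[v])
        return path[lo]

    # -- ages --------------------------------------------------------------

    def with_ages(self, ages: np.ndarray) -> "TimeTree":
        """Copy sharing topology with a replaced age vector (tips must be 0)."""
        ages = np.asarray(ages, dtype=np.float64)
        if ages.shape != (self.n_nodes,):
            raise ValueError("age vector has wrong length")
        t = object.__new__(TimeTree)
        t.__dict__.update(self.__dict__)
        t.ages = ages
        return t

    def branch_length(self, node: int) -> float:
        p = int(self.parent[node])
        if p == -1:
            raise ValueError("root has no branch")
        return float(self.ages[p] - self.ages[node])

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if self.is_tip(v):
                s = self.tip_names[v]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if self.labels[v] is not None:
                    s += self.labels[v]
            p = int(self.parent[v])
            if p != -1:
                s += ":%.17g" % (self.ages[p] - self.ages[v])
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TimeTree({self.n_tips} tips, root age "
            f"{self.ages[self.root]:.4g} Ma)"
        )


def parse_newick(text: str, tol: float = ULTRAMETRIC_TOL) -> TimeTree:
    """Parse a rooted bifurcating Newick chronogram into a :class:`TimeTree`.

    Branch lengths are chronogram lengths in Ma; node ages are computed so
    that all tips sit at age 0.  Internal node labels (after the closing
    parenthesis) are preserved and index clades for calibration attachment.

    Raises
    ------
    TreeFormatError
        If the tree contains polytomies or unifurcations, if tips are not
        contemporaneous within ``tol`` Ma, or if an internal branch has
        non-positive length (tied ages).
    """
    dt = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    dnodes = list(dt.preorder_node_iter())
    for nd in dnodes:
        nch = len(nd.child_nodes())
        if nch not in (0, 2):
            name = nd.label or (nd.taxon.label if nd.taxon else "<unnamed>")
            raise TreeFormatError(
                f"node {name!r} has {nch} children; "
                "only rooted bifurcating trees are supported"
            )

    # depths from root
    depth: dict = {}
    for nd in dnodes:
        if nd.parent_node is None:
            depth[nd] = 0.0
        else:
            bl = nd.edge.length
            depth[nd] = depth[nd.parent_node] + (0.0 if bl is None else float(bl))

    leaves = [nd for nd in dnodes if nd.is_leaf()]
    height = max(depth[nd] for nd in leaves)
    for nd in leaves:
        if abs(height - depth[nd]) > tol:
            raise TreeFormatError(
                f"tips are not contemporaneous: tip {nd.taxon.label!r} sits "
                f"{height - depth[nd]:.6g} Ma above age 0"
            )

    # index assignment: tips in newick (preorder) appearance order, then
    # internal nodes in postorder
    tip_order = [nd for nd in dnodes if nd.is_leaf()]
    internal_post = [nd for nd in dt.postorder_node_iter() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(tip_order)}
    for j, nd in enumerate(internal_post):
        index[nd] = len(tip_order) + j

    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    ages = np.zeros(n)
    labels: list[str | None] = [None] * n
    children: list[list[int]] = [[] for _ in range(n)]
    for nd in dnodes:
        i = index[nd]
        if nd.parent_node is not None:
            parent[i] = index[nd.parent_node]
            children[index[nd.parent_node]].append(i)
        if nd.is_leaf():
            ages[i] = 0.0
        else:
            ages[i] = height - depth[nd]
            labels[i] = nd.label if nd.label else None

    tree = TimeTree(
        [nd.taxon.label for nd in tip_order], parent, children, ages, labels
    )
    bad = validate_order(tree)
    if bad:
        v = bad[0]
        raise TreeFormatError(
            f"node {v.parent!r} (age {v.parent_age:.6g}) is not strictly older "
            f"than child {v.child!r} (age {v.child_age:.6g})"
        )
    return tree


def validate_order(tree: TimeTree, tol: float = ORDER_TOL) -> list[OrderViolation]:
    """All parent/child pairs violating strict ancestor-older-than-descendant.

    Returns an empty list on a valid chronogram.  Ties within ``tol`` Ma
    count as violations: zero-length internal branches break the calibration
    density machinery and are never produced by the samplers here.
    """
    out = []
    for v in range(tree.n_nodes):
        p = int(tree.parent[v])
        if p == -1:
            continue
        if not tree.ages[p] > tree.ages[v] + tol:
            out.append(
                OrderViolation(
                    tree.node_name(p),
                    tree.node_name(v),
                    float(tree.ages[p]),
                    float(tree.ages[v]),
                )
            )
    return out
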