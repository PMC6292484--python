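"""Time-calibrated trees with fossil tips.

Trees are rooted, binary (degree-2 "sampled ancestor" nodes are allowed),
and time-calibrated: branch lengths are in time units (Myr) and node ages
are measured backward from the present, so the youngest tip sits at age 0.
Tips need not be contemporaneous — a tip whose age is positive is a fossil.

Newick reading/writing is delegated to dendropy; the in-memory container is
a flat, index-based :class:`TimeTree` suited to array computation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TimeTree",
    "TraitTable",
    "StateVector",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "postorder",
    "preorder",
    "clade_nodes",
    "bind_traits",
    "read_trait_table",
]

#: relative tolerance (fraction of tree height) used to call a tip extant
EXTANT_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for structurally invalid input trees."""


@dataclass
class TimeTree:
    """Rooted time tree stored as parallel arrays indexed by node id.

    Attributes
    ----------
    parent : int array, -1 at the root
    children : tuple of tuples of child ids (empty for tips)
    blen : float array, branch length subtending each node (0.0 at root)
    label : list of node labels (tips always labelled; internal optional)
    """

    parent: np.ndarray
    children: tuple
    blen: np.ndarray
    label: list
    root: int = field(default=0)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        self._age = None
        self._postorder = None

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]],
                        dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def age(self) -> np.ndarray:
        """Node ages (time before present); youngest tip has age 0."""
        if self._age is None:
            depth = np.zeros(self.n_nodes)
            for i in preorder(self):
                if i != self.root:
                    depth[i] = depth[self.parent[i]] + self.blen[i]
            self._age = depth.max() - depth
        return self._age

    @property
    def height(self) -> float:
        return float(self.age[self.root])

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def extant_tips(self, rtol: float = EXTANT_RTOL) -> np.ndarray:
        tol = rtol * max(self.height, 1.0e-300)
        return np.array([i for i in self.tips if self.age[i] <= tol], dtype=np.int64)

    def fossil_tips(self, rtol: float = EXTANT_RTOL) -> np.ndarray:
        tol = rtol * max(self.height, 1.0e-300)
        return np.array([i for i in self.tips if self.age[i] > tol], dtype=np.int64)

    def label_to_index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.label) if lab is not None}

    def validate(self) -> None:
        if np.sum(self.parent == -1) != 1 or self.parent[self.root] != -1:
            raise TreeError("tree must have exactly one root")
        if np.any(self.blen[np.arange(self.n_nodes) != self.root] < 0):
            raise TreeError("negative branch length")
        tips = self.tips
        labs = [self.label[i] for i in tips]
        if any(l in (None, "") for l in labs):
            raise TreeError("all tips must carry non-empty labels")
        if len(set(labs)) != len(labs):
            raise TreeError("duplicate tip labels")
        for i in range(self.n_nodes):
            if len(self.children[i]) > 2:
                raise TreeError(
                    "multifurcating node %d: only binary trees are supported" % i)


@dataclass
class TraitTable:
    """Mapping of taxon label to a single continuous trait value."""

    values: dict

    def __post_init__(self):
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError("non-finite trait values for: %s" % ", ".join(map(str, bad)))

    def __getitem__(self, taxon):
        return self.values[taxon]

    def __len__(self):
        return len(self.values)


@dataclass
class StateVector:
    """Trait values at every node; tips (and sampled ancestors) are observed."""

    values: np.ndarray
    observed: np.ndarray

    def copy(self) -> "StateVector":
        return StateVector(self.values.copy(), self.observed.copy())


# ---------------------------------------------------------------------------
# Newick I/O

def _from_dendropy(dtree: dendropy.Tree) -> TimeTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    children: list = [[] for _ in range(n)]
    label: list = [None] * n
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise TreeError("missing branch length")
            parent[i] = index[id(nd.parent_node)]
            blen[i] = float(nd.edge.length)
            children[parent[i]].append(i)
        if nd.taxon is not None:
            label[i] = nd.taxon.label
        elif nd.label:
            label[i] = nd.label
    tree = TimeTree(parent, tuple(tuple(c) for c in children), blen, label, root=0)
    tree.validate()
    return tree


def read_newick(source) -> TimeTree:
    """Parse a single Newick tree from a path or a string.

    Ages are computed by root-to-tip accumulation of branch lengths; tips
    within ``EXTANT_RTOL * height`` of the maximum depth are classified as
    extant, all others as fossils. Degree-2 internal nodes are accepted
    (sampled ancestors) and may carry a label that binds a trait observation.
    """
    text = source
    if "\n" not in str(source) and not str(source).strip().endswith(";"):
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy's reader errors are not ValueErrors
        raise TreeError("could not parse Newick: %s" % exc) from exc
    return _from_dendropy(dtree)


def read_newick_list(source) -> list:
    """Parse a multi-tree file (one Newick string per line)."""
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = source
    trees = []
    for line in text.strip().splitlines():
        line = line.strip()
        if line:
            trees.append(read_newick(line))
    return trees


def write_newick(tree: TimeTree) -> str:
    """Serialize with internal node labels and full-precision branch lengths."""

    def rec(i):
        if tree.is_tip(i):
            core = _quote(tree.label[i])
        else:
            core = "(%s)" % ",".join(rec(c) for c in tree.children[i])
            if tree.label[i]:
                core += _quote(tree.label[i])
        if i == tree.root:
            return core
        return "%s:%.17g" % (core, tree.blen[i])

    return rec(tree.root) + ";"


def _quote(label):
    if label is None:
        return ""
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Traversal

def postorder(tree: TimeTree) -> np.ndarray:
    """Node ids with every child preceding its parent."""
    if tree._postorder is None:
        order = []
        stack = [(tree.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for c in tree.children[node]:
                    stack.append((c, False))
        tree._postorder = np.array(order, dtype=np.int64)
    return tree._postorder


def preorder(tree: TimeTree) -> np.ndarray:
    return postorder(tree)[::-1]


def clade_nodes(tree: TimeTree, node: int) -> set:
    """The node together with all of its descendants."""
    out = set()
    stack = [int(node)]
    while stack:
        i = stack.pop()
        out.add(i)
        stack.extend(tree.children[i])
    return out


def mrca(tree: TimeTree, nodes) -> int:
    """Most recent common ancestor of a set of node ids."""
    nodes = list(nodes)
    anc = _ancestor_path(tree, nodes[0])
    common = set(anc)
    for nd in nodes[1:]:
        common &= set(_ancestor_path(tree, nd))
    for a in anc:  # anc is ordered tipward -> rootward
        if a in common:
            return a
    return tree.root


def _ancestor_path(tree, i):
    path = [int(i)]
    while tree.parent[path[-1]] != -1:
        path.append(int(tree.parent[path[-1]]))
    return path


# ---------------------------------------------------------------------------
# Trait binding

def bind_traits(tree: TimeTree, table: TraitTable) -> StateVector:
    """Fix observed values at labelled tips (and sampled ancestors).

    Every tip label must be present in the table; labels in the table that do
    not occur in the tree are ignored with a warning. Labelled degree-2
    internal nodes (sampled ancestors) are bound as observed too.
    """
    import warnings

    n = tree.n_nodes
    values = np.zeros(n)
    observed = np.zeros(n, dtype=bool)
    missing = []
    seen = set()
    for i in range(n):
        lab = tree.label[i]
        is_sampled_ancestor = (not tree.is_tip(i)) and len(tree.children[i]) == 1
        if tree.is_tip(i) or (is_sampled_ancestor and lab is not None):
            if lab in table.values:
                values[i] = table.values[lab]
                observed[i] = True
                seen.add(lab)
            elif tree.is_tip(i):
                missing.append(lab)
    if missing:
        raise KeyError("trait values missing for tips: %s" % ", ".join(missing))
    extra = set(table.values) - seen
    if extra:
        warnings.warn("trait table labels not in tree (ignored): %s"
                      % ", ".join(sorted(map(str, extra))))
    return StateVector(values, observed)


def read_trait_table(path) -> TraitTable:
    """Read a TSV with header ``taxon<TAB>value``."""
    df = pd.read_csv(path, sep="\t")
    if not {"taxon", "value"} <= set(df.columns):
        raise ValueError("trait table needs 'taxon' and 'value' columns")
    dup = df["taxon"][df["taxon"].duplicated()]
    if len(dup):
        raise ValueError("duplicate taxa in trait table: %s" % ", ".join(dup))
    return TraitTable(dict(zip(df["taxon"].astype(str), df["value"].astype(float))))


def write_trait_table(table: TraitTable, path) -> None:
    pd.DataFrame({"taxon": list(table.values), "value": list(table.values.values())}
                 ).to_csv(path, sep="\t", index=False)
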