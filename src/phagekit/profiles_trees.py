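"""Distances between genome profiles, UPGMA dendrograms, Newick I/O and RF distance."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


class TreeError(ValueError):
    pass


@dataclass
class ProfileTable:
    row_ids: list[str]
    column_ids: list[str]
    values: np.ndarray  # shape (rows, cols), non-negative

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.column_ids)):
            raise TreeError("values shape does not match ids")
        if (self.values < 0).any():
            raise TreeError("negative entries in profile table")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise TreeError("duplicate row ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise TreeError("duplicate column ids")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise TreeError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise TreeError("distance matrix not symmetric")
        if (np.diag(self.d) != 0).any():
            raise TreeError("nonzero diagonal")
        if (self.d < 0).any():
            raise TreeError("negative distances")


@dataclass
class TreeNode:
    """Node of a rooted dendrogram; ``height`` is the ultrametric node height."""

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height):
        if self.is_leaf:
            label = self.name
        else:
            label = "(" + ",".join(
                c._newick(parent_height=self.height) for c in self.children
            ) + ")"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - self.height:.10g}"


def profile_distance(
    table: ProfileTable, metric: str = "jaccard", binarize: bool | None = None
) -> DistanceMatrix:
    """Pairwise row distances: Jaccard on presence/absence or Bray-Curtis on counts."""
    if len(table.row_ids) < 2:
        raise TreeError("need at least two rows")
    if binarize is None:
        binarize = metric == "jaccard"
    x = (table.values > 0).astype(float) if binarize else table.values
    n = len(table.row_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i], x[j]
            if metric == "jaccard":
                union = np.logical_or(a > 0, b > 0).sum()
                inter = np.logical_and(a > 0, b > 0).sum()
                dij = 0.0 if union == 0 else 1.0 - inter / union
            elif metric == "braycurtis":
                tot = (a + b).sum()
                if a.sum() == 0 or b.sum() == 0:
                    zero = table.row_ids[i] if a.sum() == 0 else table.row_ids[j]
                    raise TreeError(f"all-zero row {zero!r} with braycurtis")
                dij = np.abs(a - b).sum() / tot
            else:
                raise TreeError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=list(table.row_ids), d=d)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration with deterministic tie-breaking.

    Among all pairs at the current minimum distance the lexicographically
    smallest (by the sorted pair of smallest member labels) is merged first.
    Node heights are half the merge distance (ultrametric).
    """
    n = len(dm.ids)
    if n < 2:
        raise TreeError("need at least two ids")
    nodes = {i: TreeNode(name=dm.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    keys = {i: dm.ids[i] for i in range(n)}  # smallest member label per cluster
    dist = {frozenset((i, j)): dm.d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            dij = dist[frozenset((i, j))]
            tag = tuple(sorted((keys[i], keys[j])))
            if best is None or (dij, tag) < (best[0], best[1]):
                best = (dij, tag, i, j)
        dij, _, i, j = best
        merged = TreeNode(height=dij / 2.0, children=[nodes[i], nodes[j]])
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        keys[next_id] = min(keys[i], keys[j])
        active -= {i, j}
        for k in active:
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            dist[frozenset((next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        active.add(next_id)
        next_id += 1
    (root_id,) = active
    return nodes[root_id]


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (labels, optional branch lengths) into a TreeNode.

    Heights are reconstructed from root-to-node path lengths assuming an
    ultrametric tree: height = max leaf depth - node depth.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("newick must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node():
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            length = float(s[start:pos])
        if label and node.is_leaf:
            node.name = label
        node.height = length  # temporarily store branch length
        return node

    root = parse_node()
    if pos != len(s):
        raise TreeError(f"trailing characters in newick at {pos}")

    # convert branch lengths to ultrametric heights
    depths = {}

    def assign_depth(node, depth):
        depths[id(node)] = depth
        for c in node.children:
            assign_depth(c, depth + c.height)

    assign_depth(root, 0.0)
    maxd = max(depths[id(n)] for n in _walk(root) if n.is_leaf) if depths else 0.0

    for n in _walk(root):
        n.height = maxd - depths[id(n)]
    return root


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, each as the smaller-side leaf set frozenset."""
    all_leaves = frozenset(tree.leaves())
    out = set()
    for node in _walk(tree):
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda x: (len(x), sorted(x))))
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds symmetric difference of non-trivial bipartitions."""
    if set(t1.leaves()) != set(t2.leaves()):
        raise TreeError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)
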