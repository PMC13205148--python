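"""Neighbor-joining tree construction (Saitou–Nei) from a distance matrix.

The agglomeration criterion is Q_ij = (n-2) d_ij - r_i - r_j with
r_i = sum_k d_ik; the argmin pair is joined (ties resolved toward the
lexicographically lowest label pair), branch lengths follow the two-point
formulas, and distances update as d_uk = (d_ik + d_jk - d_ij)/2. The result
is an unrooted tree with a trifurcating top node, serialized as Newick.
On an exactly additive input matrix the induced leaf-to-leaf path lengths
reproduce the input to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .distance import DistanceMatrix


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name or ""
        parts = [f"{c._newick_inner()}:{l:.10g}" for c, l in self.children]
        label = self.name or ""
        return f"({','.join(parts)}){label}"


@dataclass
class NjTree:
    root: TreeNode               # trifurcating top node of the unrooted tree
    labels: list[str]

    def newick(self) -> str:
        return self.root.newick()

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths induced by the tree."""
        # distances from every node to all leaves via post-order accumulation
        leaf_index = {l: i for i, l in enumerate(self.labels)}
        n = len(self.labels)
        D = np.zeros((n, n))

        def down(node: TreeNode) -> dict[int, float]:
            """Map leaf index -> distance from `node`."""
            if node.is_leaf:
                return {leaf_index[node.name]: 0.0}
            maps = []
            for child, length in node.children:
                m = {k: v + length for k, v in down(child).items()}
                maps.append(m)
            for a, b in combinations(range(len(maps)), 2):
                for i, di in maps[a].items():
                    for j, dj in maps[b].items():
                        D[i, j] = D[j, i] = di + dj
            merged = {}
            for m in maps:
                merged.update(m)
            return merged

        down(self.root)
        return DistanceMatrix(D, list(self.labels))

    def cut_clades(self, n_groups: int) -> dict[str, int]:
        """Partition leaves into n_groups by removing the longest internal branches.

        Internal branches (both endpoints internal) are removed in decreasing
        length order until the leaf set falls into n_groups connected parts.
        """
        edges = []  # (length, parent, child)

        def walk(node: TreeNode) -> None:
            for child, length in node.children:
                if not child.is_leaf:
                    edges.append((length, node, child))
                walk(child)

        walk(self.root)
        edges.sort(key=lambda e: -e[0])
        cut = {id(c) for _, _, c in edges[: max(0, n_groups - 1)]}

        groups: dict[str, int] = {}
        counter = [0]

        def assign(node: TreeNode, gid: int) -> None:
            if node.is_leaf:
                groups[node.name] = gid
                return
            for child, _ in node.children:
                if id(child) in cut:
                    counter[0] += 1
                    assign(child, counter[0])
                else:
                    assign(child, gid)

        assign(self.root, 0)
        # renumber groups 1..n in first-seen leaf order
        remap, out = {}, {}
        for label in self.labels:
            g = groups[label]
            if g not in remap:
                remap[g] = len(remap) + 1
            out[label] = remap[g]
        return out


def nj_tree(dist: DistanceMatrix) -> NjTree:
    """Build the neighbor-joining tree for n >= 3 taxa."""
    n0 = dist.n
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dist.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dist.labels]
    # sort keys for the tie rule: lowest label pair
    sort_keys: list[str] = list(dist.labels)

    clamped = False
    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best, best_pair = np.inf, None
        order = sorted(range(n), key=lambda i: sort_keys[i])
        for a_pos in range(n - 1):
            for b_pos in range(a_pos + 1, n):
                i, j = order[a_pos], order[b_pos]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if q < best - 1e-15:
                    best, best_pair = q, (i, j)
        i, j = best_pair
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        sort_keys = [sort_keys[k] for k in keep] + [min(sort_keys[i], sort_keys[j])]

    a, b, c = 0, 1, 2
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    if min(la, lb, lc) < 0:
        clamped = True
        la, lb, lc = (max(v, 0.0) for v in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return NjTree(root=root, labels=list(dist.labels))
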