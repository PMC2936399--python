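"""Neighbor-joining, midpoint rooting, and cladogram conversion.

Trees are ``skbio.TreeNode`` objects.  Neighbor-joining follows the standard
Saitou-Nei agglomeration with deterministic tie-breaking (Q-criterion ties go
to the smallest (row, column) index pair), leaving an unrooted tree whose
central node trifurcates for N >= 3.  Midpoint rooting places the root
halfway along the longest leaf-to-leaf path; negative branch lengths, which
neighbor-joining can produce on non-additive input, are kept in the tree but
clamped to zero for the path metric so the diameter search stays
well-defined.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = ["neighbor_joining", "midpoint_root", "to_cladogram"]

_EPS = 1e-12


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Build an unrooted neighbor-joining tree from a distance matrix.

    Iteratively joins the pair minimizing Q(i, j) = (n-2) d_ij - r_i - r_j,
    with the standard two-point branch lengths and reduced distances.  On
    additive input the leaf-to-leaf path metric of the result reproduces the
    matrix exactly.  For N = 2 the single edge carries the full distance,
    split evenly around the connecting node.
    """
    ids = list(matrix.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    d = matrix.data.astype(float).copy()
    nodes = [TreeNode(name=name) for name in ids]

    if n == 2:
        half = d[0, 1] / 2.0
        for node in nodes:
            node.length = half
        return TreeNode(children=nodes)

    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin == smallest (row, column) pair among ties
        i, j = divmod(int(np.argmin(q)), n)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        merged = TreeNode(children=[child_i, child_j])
        # reduced distances; the merged cluster takes position i
        new_row = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = merged
        del nodes[j]
        n -= 1

    # final three clusters join at the central (trifurcating) node
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
    return TreeNode(children=nodes)


def _adjacency(tree: TreeNode):
    """Undirected adjacency {node: [(neighbor, real_length), ...]} with
    degree-2 vertices (e.g. a bifurcating root) contracted away."""
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}

    def add(u, v, length):
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))

    for node in tree.traverse(include_self=True):
        for child in node.children:
            add(node, child, child.length if child.length is not None else 0.0)

    changed = True
    while changed:
        changed = False
        for node, edges in list(adj.items()):
            if len(edges) == 2 and node.children and node.name is None:
                (u, lu), (v, lv) = edges
                adj[u] = [(w, l) for (w, l) in adj[u] if w is not node]
                adj[v] = [(w, l) for (w, l) in adj[v] if w is not node]
                del adj[node]
                add(u, v, lu + lv)
                changed = True
                break
    return adj


def _tip_distances(adj, tips):
    """Clamped-length path distances from each tip to every node."""
    dist = {}
    for tip in tips:
        d = {tip: 0.0}
        stack = [tip]
        while stack:
            u = stack.pop()
            for v, length in adj[u]:
                if v not in d:
                    d[v] = d[u] + max(length, 0.0)
                    stack.append(v)
        dist[tip] = d
    return dist


def _path(adj, a, b):
    """List of (node, real_length_to_next) along the a→b path."""
    parent = {a: None}
    stack = [a]
    while stack:
        u = stack.pop()
        if u is b:
            break
        for v, length in adj[u]:
            if v not in parent:
                parent[v] = (u, length)
                stack.append(v)
    nodes = [b]
    lengths = []
    u = b
    while parent[u] is not None:
        p, length = parent[u]
        nodes.append(p)
        lengths.append(length)
        u = p
    nodes.reverse()
    lengths.reverse()
    return nodes, lengths


def _rebuild(adj, root, root_extra=None):
    """Materialize a rooted TreeNode from the adjacency, hanging from ``root``.

    ``root_extra``: (u, xu, v, xv) describes a root inserted inside edge
    (u, v), at real distance xu from u and xv from v.
    """

    def build(vertex, parent):
        node = TreeNode(name=vertex.name)
        for neighbor, length in adj[vertex]:
            if neighbor is parent:
                continue
            child = build(neighbor, vertex)
            child.length = length
            node.append(child)
        return node

    if root_extra is None:
        new_root = TreeNode(name=root.name)
        for neighbor, length in adj[root]:
            child = build(neighbor, root)
            child.length = length
            new_root.append(child)
        return new_root
    u, xu, v, xv = root_extra
    new_root = TreeNode()
    left = build(u, v)
    left.length = xu
    right = build(v, u)
    right.length = xv
    new_root.append(left)
    new_root.append(right)
    return new_root


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root an unrooted tree halfway along its longest leaf-to-leaf path.

    Branch lengths are required; negative lengths count as zero in the path
    metric.  Diameter ties are broken by the lexicographically smallest
    endpoint label pair, and if the midpoint coincides with an existing node
    that node becomes the root.
    """
    tree = tree.copy()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("midpoint rooting requires branch lengths")
    tips = sorted(tree.tips(), key=lambda t: t.name)
    if len(tips) < 2:
        raise ValueError("midpoint rooting requires at least 2 leaves")
    adj = _adjacency(tree)
    dist = _tip_distances(adj, tips)

    diameter = max(dist[a][b] for i, a in enumerate(tips) for b in tips[i + 1 :])
    best = min(
        (a.name, b.name)
        for i, a in enumerate(tips)
        for b in tips[i + 1 :]
        if dist[a][b] >= diameter - _EPS
    )
    by_name = {t.name: t for t in tips}
    start, end = by_name[best[0]], by_name[best[1]]

    nodes, lengths = _path(adj, start, end)
    half = diameter / 2.0
    cum = 0.0
    for k, length in enumerate(lengths):
        clamped = max(length, 0.0)
        if cum + clamped < half - _EPS:
            cum += clamped
            continue
        x = half - cum
        if x <= _EPS:
            return _rebuild(adj, nodes[k])
        if clamped - x <= _EPS:
            return _rebuild(adj, nodes[k + 1])
        u, v = nodes[k], nodes[k + 1]
        adj[u] = [(w, l) for (w, l) in adj[u] if w is not v]
        adj[v] = [(w, l) for (w, l) in adj[v] if w is not u]
        return _rebuild(adj, None, root_extra=(u, x, v, length - x))
    return _rebuild(adj, nodes[-1])  # degenerate: zero diameter


def to_cladogram(tree: TreeNode) -> TreeNode:
    """Copy of a rooted tree with every branch length discarded."""
    out = tree.copy()
    for node in out.traverse(include_self=True):
        node.length = None
    return out
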