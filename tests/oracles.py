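"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the LZ oracle rebuilds
each production step by exhaustive substring search over every candidate
prefix, and the path-length oracle walks the tree as a plain weighted graph.
"""

from __future__ import annotations

import networkx as nx


def reproducible(candidate: str, generated: str) -> bool:
    """True if ``candidate`` can be produced by copying from ``generated``,
    allowing the copy window to slide into ``candidate`` itself."""
    return candidate in (generated + candidate[:-1])


def lz_history_bruteforce(s: str) -> list[str]:
    """LZ76 exhaustive history via exhaustive substring search.

    For every step, tests reproducibility of *every* candidate prefix of the
    remainder and takes the longest, then appends the innovation symbol.
    Quadratic per step; for test-scale strings only.
    """
    components: list[str] = []
    generated = ""
    rest = s
    while rest:
        ok_lengths = [
            m for m in range(1, len(rest) + 1) if reproducible(rest[:m], generated)
        ]
        longest = max(ok_lengths, default=0)
        if longest == len(rest):
            components.append(rest)
            break
        component = rest[: longest + 1]
        components.append(component)
        generated += component
        rest = rest[longest + 1 :]
    return components


def tree_graph(tree, clamp: bool = False) -> nx.Graph:
    """A tree as an undirected weighted graph keyed by node identity."""
    g = nx.Graph()
    for node in tree.traverse(include_self=True):
        for child in node.children:
            w = child.length if child.length is not None else 0.0
            if clamp:
                w = max(w, 0.0)
            g.add_edge(id(node), id(child), weight=w)
    return g


def leaf_path_lengths(tree, clamp: bool = False) -> dict:
    """All-pairs leaf-to-leaf path lengths by graph shortest paths."""
    g = tree_graph(tree, clamp=clamp)
    tips = {id(t): t.name for t in tree.tips()}
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    out = {}
    names = sorted(tips.items(), key=lambda kv: kv[1])
    for i, (ka, a) in enumerate(names):
        for kb, b in names[i + 1 :]:
            out[(a, b)] = lengths[ka][kb]
    return out
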