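"""Tree-Based Classification (TBC) of subfamilies on a rooted tree.

TBC partitions the leaves of a rooted tree (cladogram is fine — no branch
lengths are used) by assigning each expert-labelled subfamily to at most one
clade.  A clade is eligible for a subfamily when both contamination ratios
stay at or below the maximal allowed level of 0.5:

    fp / (tp + fp) <= 0.5   (clade impurity)
    fn / (tp + fn) <= 0.5   (subfamily leakage)

with tp the subfamily members inside the clade, fp the other leaves inside,
and fn the members left outside.  Selected clades must be pairwise disjoint
and the selection maximizes the total number of true positives.  The default
solver is a deterministic greedy (candidates by tp descending, then smaller
clade, then subfamily name); an exact exhaustive solver over candidate
subsets is available for small instances as an oracle.

Each leaf is then scored once: a true positive inside its own subfamily's
clade, misclassified inside another subfamily's clade, unclassified
otherwise; accuracy = 1 - (misclassified + unclassified) / N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio import TreeNode

__all__ = [
    "MAX_CONTAMINATION",
    "CladeCandidate",
    "TBCResult",
    "enumerate_clades",
    "tbc_classify",
    "tbc_accuracy",
    "write_report",
]

MAX_CONTAMINATION = 0.5


@dataclass(frozen=True)
class CladeCandidate:
    """One (clade, subfamily) pairing with its confusion counts."""

    clade: frozenset
    subfamily: str
    tp: int
    fp: int
    fn: int

    @property
    def fp_ratio(self) -> float:
        return self.fp / (self.tp + self.fp)

    @property
    def fn_ratio(self) -> float:
        return self.fn / (self.tp + self.fn)

    @property
    def eligible(self) -> bool:
        return (
            self.tp > 0
            and self.fp_ratio <= MAX_CONTAMINATION
            and self.fn_ratio <= MAX_CONTAMINATION
        )


@dataclass
class TBCResult:
    """Assignments, per-leaf verdicts, and overall accuracy of one TBC run."""

    assignments: dict  # subfamily -> frozenset of leaf ids, or None
    candidates: dict  # subfamily -> CladeCandidate for the assigned clade
    verdicts: dict  # leaf id -> "tp" | "misclassified" | "unclassified"
    n_leaves: int

    @property
    def misclassified(self) -> int:
        return sum(v == "misclassified" for v in self.verdicts.values())

    @property
    def unclassified(self) -> int:
        return sum(v == "unclassified" for v in self.verdicts.values())

    @property
    def error_count(self) -> int:
        return self.misclassified + self.unclassified

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error_count / self.n_leaves


def enumerate_clades(tree: TreeNode) -> list[frozenset]:
    """Leaf-id set of every node of a rooted tree, in preorder.

    Leaves give singletons and the root gives the full leaf set.  A tree
    whose root has more than two children is considered unrooted and
    rejected.
    """
    if len(tree.children) > 2:
        raise ValueError("enumerate_clades requires a rooted (bifurcating) tree")
    clades = []
    for node in tree.preorder(include_self=True):
        clades.append(frozenset(tip.name for tip in node.tips(include_self=True)))
    return clades


def _candidates(clades, attributes):
    members: dict[str, set] = {}
    for leaf, subfamily in attributes.items():
        members.setdefault(subfamily, set()).add(leaf)
    out = []
    for clade in clades:
        for subfamily, mem in members.items():
            tp = len(clade & mem)
            cand = CladeCandidate(
                clade=clade,
                subfamily=subfamily,
                tp=tp,
                fp=len(clade) - tp,
                fn=len(mem) - tp,
            )
            if cand.eligible:
                out.append(cand)
    return out


def _sort_key(c: CladeCandidate):
    return (-c.tp, len(c.clade), c.subfamily, tuple(sorted(c.clade)))


def _greedy_select(candidates):
    chosen: list[CladeCandidate] = []
    taken_subfamilies: set[str] = set()
    taken_leaves: set = set()
    for cand in sorted(candidates, key=_sort_key):
        if cand.subfamily in taken_subfamilies:
            continue
        if cand.clade & taken_leaves:
            continue
        chosen.append(cand)
        taken_subfamilies.add(cand.subfamily)
        taken_leaves |= cand.clade
    return chosen


def _exact_select(candidates):
    """Exhaustive search over pairwise-disjoint, one-per-subfamily candidate
    subsets, maximizing total tp.  Exponential; intended for small instances
    (the greedy solver's oracle)."""
    order = sorted(candidates, key=_sort_key)
    best: list[CladeCandidate] = []
    best_tp = -1

    def rest_tp(k):  # optimistic bound
        return sum(c.tp for c in order[k:])

    def search(k, chosen, chosen_tp, subfams, leaves):
        nonlocal best, best_tp
        if chosen_tp + rest_tp(k) <= best_tp:
            return
        if k == len(order):
            if chosen_tp > best_tp:
                best = list(chosen)
                best_tp = chosen_tp
            return
        cand = order[k]
        if cand.subfamily not in subfams and not (cand.clade & leaves):
            chosen.append(cand)
            search(
                k + 1,
                chosen,
                chosen_tp + cand.tp,
                subfams | {cand.subfamily},
                leaves | cand.clade,
            )
            chosen.pop()
        search(k + 1, chosen, chosen_tp, subfams, leaves)

    search(0, [], 0, set(), frozenset())
    return best


def tbc_classify(tree: TreeNode, attributes: dict, solver: str = "greedy") -> TBCResult:
    """Run TBC on a rooted tree given a leaf→subfamily attribute table."""
    leaves = [tip.name for tip in tree.tips(include_self=True)]
    if not leaves:
        raise ValueError("empty tree")
    missing = [leaf for leaf in leaves if leaf not in attributes]
    if missing:
        raise ValueError(f"leaves missing from attribute table: {sorted(missing)}")

    clades = enumerate_clades(tree)
    candidates = _candidates(clades, {leaf: attributes[leaf] for leaf in leaves})
    if solver == "greedy":
        chosen = _greedy_select(candidates)
    elif solver == "exact":
        chosen = _exact_select(candidates)
    else:
        raise ValueError(f"unknown solver {solver!r}")

    # hard invariant: selected clades pairwise disjoint
    seen: set = set()
    for cand in chosen:
        assert not (cand.clade & seen), "selected clades overlap"
        seen |= cand.clade

    subfamilies = sorted(set(attributes[leaf] for leaf in leaves))
    assignments = {s: None for s in subfamilies}
    by_subfamily = {}
    for cand in chosen:
        assignments[cand.subfamily] = cand.clade
        by_subfamily[cand.subfamily] = cand

    leaf_to_clade_subfamily = {}
    for cand in chosen:
        for leaf in cand.clade:
            leaf_to_clade_subfamily[leaf] = cand.subfamily

    verdicts = {}
    for leaf in leaves:
        where = leaf_to_clade_subfamily.get(leaf)
        if where is None:
            verdicts[leaf] = "unclassified"
        elif where == attributes[leaf]:
            verdicts[leaf] = "tp"
        else:
            verdicts[leaf] = "misclassified"

    return TBCResult(
        assignments=assignments,
        candidates=by_subfamily,
        verdicts=verdicts,
        n_leaves=len(leaves),
    )


def tbc_accuracy(result: TBCResult) -> float:
    """Accuracy as a percentage, rounded to one decimal (e.g. 97.2)."""
    return round(100.0 * result.accuracy, 1)


def write_report(result: TBCResult, path) -> None:
    """Per-subfamily TSV report (clade size, tp/fp/fn) plus overall accuracy."""
    with open(path, "w") as fh:
        fh.write("subfamily\tclade_size\ttp\tfp\tfn\n")
        for subfamily in sorted(result.assignments):
            cand = result.candidates.get(subfamily)
            if cand is None:
                fh.write(f"{subfamily}\t0\t0\t0\tNA\n")
            else:
                fh.write(
                    f"{subfamily}\t{len(cand.clade)}\t{cand.tp}\t{cand.fp}\t{cand.fn}\n"
                )
        fh.write(f"# leaves\t{result.n_leaves}\n")
        fh.write(f"# misclassified\t{result.misclassified}\n")
        fh.write(f"# unclassified\t{result.unclassified}\n")
        fh.write(f"# accuracy_percent\t{tbc_accuracy(result)}\n")
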