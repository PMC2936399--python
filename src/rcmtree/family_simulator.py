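"""Synthetic protein families with known true trees and subfamily structure.

Sequences evolve from a random root along a rooted tree with branch lengths
in expected-substitutions-per-site units: each site substitutes with
probability 1 - exp(-r t) along a branch of length t, targets drawn from an
exchangeability table (uniform over the other 19 residues by default, with a
hook for any 20x20 table).  Indel events arrive as a Poisson process at rate
``indel_rate`` relative to the substitution process, split evenly between
insertions and deletions, with lengths from a discrete power law
P(L) ∝ L^(-a) truncated at ``max_indel`` and placement uniform along the
sequence.  Defaults mirror a standard simulated benchmark: root length 500,
indel rate 0.1, power-law exponent a = 1.7, maximum indel length 500.

Everything is deterministic given the seed: same seed, byte-identical FASTA,
attribute table, and true tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skbio import TreeNode

from .alphabets import STANDARD_RESIDUES
from .io_formats import SequenceRecord, write_attributes, write_fasta, write_newick

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "random_tree",
    "simulate_along_tree",
    "simulate_subfamily_structure",
]

_N_RES = len(STANDARD_RESIDUES)
_RES = np.frombuffer(STANDARD_RESIDUES.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the sequence-evolution process.

    ``substitution_rate`` is in expected substitutions per site per unit of
    branch length (1.0 means branch lengths *are* substitutions/site);
    ``indel_rate`` is relative to the substitution process; ``exchange``
    optionally supplies a 20x20 row-stochastic substitution-target table
    (rows indexed by source residue in ``STANDARD_RESIDUES`` order, zero
    diagonal).
    """

    root_length: int = 500
    substitution_rate: float = 1.0
    indel_rate: float = 0.1
    powerlaw_a: float = 1.7
    max_indel: int = 500
    seed: int = 0
    exchange: object = None  # optional (20, 20) array

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")
        if self.powerlaw_a <= 1:
            raise ValueError("powerlaw_a must be > 1")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")
        if self.exchange is not None:
            ex = np.asarray(self.exchange, dtype=float)
            if ex.shape != (_N_RES, _N_RES):
                raise ValueError("exchange table must be 20x20")


@dataclass
class SimulatedFamily:
    """A simulated family: sequence records, leaf→subfamily attributes, and
    the rooted true tree (with branch lengths) the sequences evolved along."""

    records: list
    attributes: dict
    true_tree: TreeNode

    def write(self, fasta_path, attributes_path, tree_path) -> None:
        write_fasta(self.records, fasta_path)
        write_attributes(self.attributes, attributes_path)
        write_newick(self.true_tree, tree_path, with_branch_lengths=True)


def random_tree(
    n_taxa: int,
    rng,
    branch_length_range=(0.04, 0.06),
    names=None,
) -> TreeNode:
    """Random rooted binary tree over ``n_taxa`` leaves.

    Topology by uniform random pair joins; every branch length drawn
    uniformly from ``branch_length_range``.  The default range gives
    moderate, well-separated branches (a few percent divergence per branch,
    far from both zero and saturation), the regime in which distance-based
    reconstruction is informative.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(rng)
    if names is None:
        names = [f"t{i + 1}" for i in range(n_taxa)]
    lo, hi = branch_length_range
    nodes = [TreeNode(name=name) for name in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent = TreeNode(children=[a, b])
        nodes[i] = parent
        del nodes[j]
    root = nodes[0]
    root.length = None
    return root


def _powerlaw_cdf(a: float, max_len: int) -> np.ndarray:
    pmf = np.arange(1, max_len + 1, dtype=float) ** (-a)
    pmf /= pmf.sum()
    return np.cumsum(pmf)


def sample_indel_lengths(rng, a: float, max_len: int, size: int) -> np.ndarray:
    """Draw indel lengths from the truncated discrete power law by inverse CDF."""
    cdf = _powerlaw_cdf(a, max_len)
    return np.searchsorted(cdf, rng.random(size)) + 1


def _evolve_branch(seq: np.ndarray, t: float, config: SimulationConfig, rng) -> np.ndarray:
    """Evolve one sequence (uint8 residue indices) along a branch of length t."""
    if t < 0:
        raise ValueError("negative branch length")
    r = config.substitution_rate
    if r > 0 and t > 0 and len(seq):
        p_sub = 1.0 - np.exp(-r * t)
        mask = rng.random(len(seq)) < p_sub
        n_sub = int(mask.sum())
        if n_sub:
            if config.exchange is None:
                # uniform over the other 19 residues
                draw = rng.integers(0, _N_RES - 1, size=n_sub)
                old = seq[mask]
                seq = seq.copy()
                seq[mask] = draw + (draw >= old)
            else:
                ex = np.asarray(config.exchange, dtype=float)
                seq = seq.copy()
                idx = np.flatnonzero(mask)
                for k in idx:
                    seq[k] = rng.choice(_N_RES, p=ex[seq[k]] / ex[seq[k]].sum())
    if config.indel_rate > 0 and t > 0:
        n_events = rng.poisson(config.indel_rate * r * t * len(seq))
        for _ in range(n_events):
            insert = rng.random() < 0.5
            length = int(sample_indel_lengths(rng, config.powerlaw_a, config.max_indel, 1)[0])
            if insert:
                pos = int(rng.integers(0, len(seq) + 1))
                content = rng.integers(0, _N_RES, size=length).astype(np.uint8)
                seq = np.concatenate([seq[:pos], content, seq[pos:]])
            elif len(seq):
                pos = int(rng.integers(0, len(seq)))
                seq = np.concatenate([seq[:pos], seq[pos + length :]])
            if not len(seq):
                # an extreme deletion emptied the sequence; keep one residue
                seq = rng.integers(0, _N_RES, size=1).astype(np.uint8)
    return seq


def _indices_to_str(seq: np.ndarray) -> str:
    return _RES[seq].tobytes().decode()


def simulate_along_tree(
    tree: TreeNode,
    config: SimulationConfig,
    attributes: dict | None = None,
) -> SimulatedFamily:
    """Evolve sequences along a rooted tree with branch lengths.

    Leaves must be uniquely named; ``attributes`` defaults to a single
    subfamily label ``"family"`` for every leaf.  Deterministic given
    ``config.seed``; the tree is traversed in preorder with children in
    their stored order.
    """
    tips = [tip.name for tip in tree.tips(include_self=True)]
    if len(set(tips)) != len(tips):
        raise ValueError("leaf names must be unique")
    if not tips:
        raise ValueError("empty tree")
    rng = np.random.default_rng(config.seed)
    root_seq = rng.integers(0, _N_RES, size=config.root_length).astype(np.uint8)

    records: list[SequenceRecord] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            child_seq = _evolve_branch(seq, float(t), config, rng)
            if child.is_tip():
                residues = _indices_to_str(child_seq)
                records.append(
                    SequenceRecord(
                        id=child.name, residues=residues, source_length=len(residues)
                    )
                )
            else:
                descend(child, child_seq)

    if tree.is_tip():
        residues = _indices_to_str(root_seq)
        records.append(
            SequenceRecord(id=tree.name, residues=residues, source_length=len(residues))
        )
    else:
        descend(tree, root_seq)

    if attributes is None:
        attributes = {name: "family" for name in tips}
    return SimulatedFamily(records=records, attributes=dict(attributes), true_tree=tree)


def _random_subtree(names, scale, rng) -> TreeNode:
    """Random binary tree over ``names`` with edge lengths ~ scale·U(0.75, 1.25)."""
    nodes = [TreeNode(name=n) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(scale * rng.uniform(0.75, 1.25))
        b.length = float(scale * rng.uniform(0.75, 1.25))
        nodes[i] = TreeNode(children=[a, b])
        del nodes[j]
    return nodes[0]


def simulate_subfamily_structure(
    n_subfamilies: int,
    members_per_subfamily,
    deep_divergence: float,
    shallow_divergence: float,
    config: SimulationConfig,
) -> SimulatedFamily:
    """Simulate a family of ``n_subfamilies`` subfamilies with deep
    between-subfamily and shallow within-subfamily divergence.

    Subfamily ancestors are joined in a random binary tree whose edges are on
    the ``deep_divergence`` scale; each subfamily's members coalesce in a
    random binary subtree on the ``shallow_divergence`` scale.
    ``members_per_subfamily`` is an int or a per-subfamily list.
    """
    if n_subfamilies < 2:
        raise ValueError("need at least 2 subfamilies")
    if not deep_divergence > shallow_divergence > 0:
        raise ValueError("require deep_divergence > shallow_divergence > 0")
    if isinstance(members_per_subfamily, int):
        sizes = [members_per_subfamily] * n_subfamilies
    else:
        sizes = list(members_per_subfamily)
        if len(sizes) != n_subfamilies:
            raise ValueError("one size per subfamily required")
    if any(s < 1 for s in sizes):
        raise ValueError("subfamily sizes must be >= 1")
    if all(s == 1 for s in sizes):
        raise ValueError("at least one subfamily must have more than one member")

    rng = np.random.default_rng(config.seed)
    attributes: dict[str, str] = {}
    subtrees = []
    for j, size in enumerate(sizes):
        label = f"SF{j + 1}"
        names = [f"{label}_{i + 1}" for i in range(size)]
        for name in names:
            attributes[name] = label
        if size == 1:
            sub = TreeNode(name=names[0])
        else:
            sub = _random_subtree(names, shallow_divergence, rng)
        subtrees.append(sub)

    nodes = subtrees
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(deep_divergence * rng.uniform(0.75, 1.25))
        b.length = float(deep_divergence * rng.uniform(0.75, 1.25))
        nodes[i] = TreeNode(children=[a, b])
        del nodes[j]
    tree = nodes[0]
    tree.length = None

    # sequence evolution consumes a child generator seeded deterministically
    seq_config = replace(config, seed=int(np.random.default_rng(config.seed).integers(2**31)))
    fam = simulate_along_tree(tree, seq_config, attributes=attributes)
    return fam
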