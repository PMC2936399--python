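"""Reduced amino-acid alphabets (RAAAs) and sequence recoding.

An alphabet is a partition of the 20 standard amino acids into named groups;
recoding replaces every residue by its group's representative (the
alphabetically first residue of the group), so recoded sequences remain plain
amino-acid strings writable as FASTA.  Built-in schemes are shipped as
editable data files; seeded random partitions of any size are available as a
control.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "BUILTIN_ALPHABETS",
    "Alphabet",
    "load_alphabet",
    "parse_alphabet_text",
    "random_alphabet",
    "recode",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Built-in scheme identifiers, in the conventional reporting order:
#: identity, then reduction schemes by family and size.
BUILTIN_ALPHABETS = (
    "ID20",
    "ML4",
    "ML8",
    "ML10",
    "ML15",
    "EB5",
    "EB8",
    "EB9",
    "EB11",
    "EB13",
    "SDM12",
    "HSDM17",
    "GBMR4",
)


@dataclass(frozen=True)
class Alphabet:
    """A partition of the 20 standard amino acids into ``k`` groups."""

    name: str
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError(f"alphabet {self.name!r}: empty group")
            for r in g:
                if r not in STANDARD_RESIDUES:
                    raise ValueError(
                        f"alphabet {self.name!r}: {r!r} is not a standard residue"
                    )
                if r in seen:
                    raise ValueError(
                        f"alphabet {self.name!r}: residue {r!r} in two groups"
                    )
                seen.add(r)
        if seen != set(STANDARD_RESIDUES):
            missing = sorted(set(STANDARD_RESIDUES) - seen)
            raise ValueError(
                f"alphabet {self.name!r}: not a partition, missing {missing}"
            )
        if not 2 <= len(self.groups) <= 20:
            raise ValueError(f"alphabet {self.name!r}: size must be in [2, 20]")

    @property
    def size(self) -> int:
        return len(self.groups)

    @property
    def representatives(self) -> tuple[str, ...]:
        """One symbol per group: the alphabetically first residue."""
        return tuple(min(g) for g in self.groups)

    @property
    def translation(self) -> dict[int, int]:
        """``str.translate`` table mapping each residue to its representative."""
        table: dict[int, int] = {}
        for g, rep in zip(self.groups, self.representatives):
            for r in g:
                table[ord(r)] = ord(rep)
        return table


def parse_alphabet_text(text: str, name: str) -> Alphabet:
    """Parse an alphabet definition: one group per line, residues concatenated,
    ``#`` comment lines and blank lines ignored."""
    groups = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            groups.append(line.upper())
    if not groups:
        raise ValueError(f"alphabet {name!r}: no groups defined")
    return Alphabet(name=name, groups=tuple(groups))


def _builtin_text(name: str) -> str:
    ref = resources.files("rcmtree.data.alphabets") / f"{name}.txt"
    return ref.read_text()


def load_alphabet(name: str) -> Alphabet:
    """Load a built-in alphabet by identifier, or a custom one from a path.

    Built-ins: ID20 (identity) plus the reduction schemes in
    ``BUILTIN_ALPHABETS``.  Any other argument is treated as a path to an
    alphabet definition file.
    """
    if name == "ID20":
        return Alphabet(name="ID20", groups=tuple(STANDARD_RESIDUES))
    if name in BUILTIN_ALPHABETS:
        alpha = parse_alphabet_text(_builtin_text(name), name)
        declared = int("".join(c for c in name if c.isdigit()))
        if alpha.size != declared:
            raise ValueError(
                f"built-in alphabet {name!r} defines {alpha.size} groups, "
                f"expected {declared}"
            )
        return alpha
    path = Path(name)
    if path.exists():
        return parse_alphabet_text(path.read_text(), name=path.stem)
    raise ValueError(
        f"unknown alphabet {name!r}: not a built-in "
        f"({', '.join(BUILTIN_ALPHABETS)}) and no such file"
    )


def _stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind, S(n, k)."""
    table = [[0] * (k + 1) for _ in range(n + 1)]
    table[0][0] = 1
    for i in range(1, n + 1):
        for j in range(1, min(i, k) + 1):
            table[i][j] = j * table[i - 1][j] + table[i - 1][j - 1]
    return table[n][k]


def random_alphabet(k: int, seed: int) -> Alphabet:
    """A uniformly random partition of the 20 residues into exactly ``k``
    non-empty groups, deterministic given ``seed``.

    Sampled exactly via the Stirling-number recursion (element n is a new
    singleton block with probability S(n-1, k-1)/S(n, k), otherwise it joins
    one of the k blocks of a uniform partition of the remaining elements),
    so every partition into exactly ``k`` blocks is equally likely — naive
    rejection of empty-group assignments would be astronomically slow as
    ``k`` approaches 20.
    """
    if not 2 <= k <= 20:
        raise ValueError("k must be in [2, 20]")
    rng = np.random.default_rng(seed)

    def sample(n: int, groups: int) -> list[set]:
        if groups == n:
            return [{i} for i in range(n)]
        if groups == 1:
            return [set(range(n))]
        p_singleton = _stirling2(n - 1, groups - 1) / _stirling2(n, groups)
        if rng.random() < p_singleton:
            blocks = sample(n - 1, groups - 1)
            blocks.append({n - 1})
        else:
            blocks = sample(n - 1, groups)
            blocks[int(rng.integers(groups))].add(n - 1)
        return blocks

    blocks = sample(20, k)
    groups = tuple(
        sorted("".join(STANDARD_RESIDUES[i] for i in sorted(block)) for block in blocks)
    )
    return Alphabet(name=f"RANDOM{k}-{seed}", groups=groups)


def recode(record, alphabet: Alphabet):
    """Replace each residue of a sequence record by its group representative.

    Length and id are preserved.  Raises on residues outside the 20 standard
    amino acids (clean the record first).
    """
    from .io_formats import SequenceRecord

    bad = set(record.residues) - set(STANDARD_RESIDUES)
    if bad:
        raise ValueError(
            f"record {record.id!r}: residues {sorted(bad)} not covered by "
            f"alphabet {alphabet.name!r}"
        )
    return SequenceRecord(
        id=record.id,
        residues=record.residues.translate(alphabet.translation),
        source_length=record.source_length,
    )
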