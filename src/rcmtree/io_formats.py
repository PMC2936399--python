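"""Readers and writers for the pipeline's on-disk formats.

FASTA (via Biopython), two-column tab-separated leaf→subfamily attribute
tables, PHYLIP-style square distance matrices, and Newick trees (via
scikit-bio).  Sequence cleaning follows the discard policy used for the
curated families: gap characters and any symbol outside the 20 standard
amino acids are removed, with per-record counts reported.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode

from .alphabets import STANDARD_RESIDUES

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "read_attributes",
    "write_attributes",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_newick",
    "write_newick",
]

logger = logging.getLogger(__name__)

_STANDARD = set(STANDARD_RESIDUES)
_GAPS = {"-", "."}


@dataclass(frozen=True)
class SequenceRecord:
    """One named protein sequence.

    ``source_length`` counts the residues before cleaning, so
    ``source_length - len(residues)`` is the number of removed symbols.
    """

    id: str
    residues: str
    source_length: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def removed(self) -> int:
        return self.source_length - len(self.residues)


def clean_residues(raw: str, policy: str = "discard") -> str:
    """Upper-case ``raw`` and apply the cleaning policy.

    ``discard`` removes gap characters and any symbol outside the 20 standard
    amino acids; ``strict`` raises instead of editing; ``none`` only
    upper-cases.
    """
    s = raw.upper()
    if policy == "none":
        return s
    kept = [c for c in s if c in _STANDARD]
    if policy == "discard":
        return "".join(kept)
    if policy == "strict":
        bad = [c for c in s if c not in _STANDARD]
        if bad:
            raise ValueError(f"non-standard symbols {sorted(set(bad))} in sequence")
        return s
    raise ValueError(f"unknown cleaning policy {policy!r}")


def read_fasta(path, cleaning_policy: str = "discard") -> list[SequenceRecord]:
    """Read a FASTA file into cleaned ``SequenceRecord`` objects, in file order.

    Duplicate ids, an empty file, and records left empty by cleaning are
    errors; the number of removed symbols is logged per record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        residues = clean_residues(raw, cleaning_policy)
        record = SequenceRecord(id=rec.id, residues=residues, source_length=len(raw))
        if not record.residues:
            raise ValueError(f"record {rec.id!r} has no residues after cleaning")
        if record.removed:
            logger.info(
                "record %s: removed %d non-standard symbol(s)",
                record.id,
                record.removed,
            )
        records.append(record)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_attributes(path) -> dict[str, str]:
    """Read a two-column tab-separated id→subfamily table."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id<TAB>subfamily', got {line!r}"
                )
            seq_id, subfamily = parts
            if seq_id in table and table[seq_id] != subfamily:
                raise ValueError(
                    f"{path}:{lineno}: id {seq_id!r} mapped to both "
                    f"{table[seq_id]!r} and {subfamily!r}"
                )
            table[seq_id] = subfamily
    if not table:
        raise ValueError(f"attribute table {path} is empty")
    return table


def write_attributes(table: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for seq_id, subfamily in table.items():
            fh.write(f"{seq_id}\t{subfamily}\n")


def _check_square(matrix: DistanceMatrix) -> None:
    data = matrix.data
    if np.isnan(data).any():
        raise ValueError("distance matrix contains NaN entries")
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix is not symmetric")


def write_distance_matrix(matrix: DistanceMatrix, path, dialect: str = "relaxed") -> None:
    """Write a square distance matrix.

    ``phylip``: taxon count on line 1, names padded/truncated to 10
    characters (collisions after truncation are an error), 6-decimal values.
    ``relaxed``: untruncated names, full-precision values.
    """
    _check_square(matrix)
    ids = list(matrix.ids)
    if dialect == "phylip":
        names = [f"{i[:10]:<10}" for i in ids]
        if len({n for n in names}) != len(names):
            raise ValueError("taxon names collide after 10-character truncation")
        fmt = "{:.6f}"
    elif dialect == "relaxed":
        names = [f"{i}  " for i in ids]
        fmt = "{:.10g}"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for name, row in zip(names, matrix.data):
            fh.write(name + " ".join(fmt.format(v) for v in row) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a PHYLIP-style square distance matrix (either dialect)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 1 or not header[0].isdigit():
            raise ValueError(f"{path}: first line must be the taxon count")
        n = int(header[0])
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != n + 1:
                raise ValueError(
                    f"{path}: row for {parts[0]!r} has {len(parts) - 1} values, "
                    f"expected {n}"
                )
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(ids) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(ids)}")
    data = np.asarray(rows)
    # symmetrize away decimal-format round-off, but reject real asymmetry
    if not np.allclose(data, data.T, atol=1e-6):
        raise ValueError(f"{path}: matrix is not symmetric")
    data = (data + data.T) / 2.0
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids)


def write_newick(tree: TreeNode, path, with_branch_lengths: bool = True) -> None:
    """Write a tree in Newick format; optionally drop every branch length."""
    out = tree
    if not with_branch_lengths:
        out = tree.copy()
        for node in out.traverse():
            node.length = None
    out.write(str(path))


def read_newick(path) -> TreeNode:
    try:
        return TreeNode.read(str(path), convert_underscores=False)
    except Exception as exc:  # skbio raises several parser error types
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc
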