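"""Pairwise relative-complexity distance matrices.

Recodes a sequence set once under the chosen reduced alphabet, then computes
the normalized LZ distance for each unordered pair, caching per-sequence
complexities.  The diagonal is forced to zero: the raw formula gives a small
positive self-distance (2(c(xx) - c(x))/c(xx)), but neighbor-joining and the
PHYLIP format require a hollow matrix.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from skbio import DistanceMatrix

from .alphabets import Alphabet, recode
from .lz_core import lz_complexity, rcm_distance

__all__ = ["pairwise_rcm"]


def pairwise_rcm(records, alphabet: Alphabet | None = None) -> DistanceMatrix:
    """Symmetric RCM distance matrix over ``records``.

    If ``alphabet`` is given, records are recoded under it first; labels and
    their order follow the input records.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("pairwise_rcm requires at least 2 records")
    if alphabet is not None:
        records = [recode(r, alphabet) for r in records]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = [r.residues for r in records]
    c = [lz_complexity(s) for s in seqs]
    n = len(seqs)
    data = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = rcm_distance(seqs[i], seqs[j], c_x=c[i], c_y=c[j]).value
        data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids)
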