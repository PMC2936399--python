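"""Lempel-Ziv exhaustive-history complexity and the relative complexity distance.

The LZ76 *exhaustive history* of a string is its unique production parse:
each step copies the longest stretch reproducible from the text generated so
far (the copy may overlap the component being produced) and then appends one
new symbol — the innovation.  The final component may be fully reproducible
and carry no innovation.  The number of components is the LZ complexity
``c(s)``; comparing ``c`` of two sequences with the ``c`` of their
concatenations yields a normalized, alignment-free distance between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ExhaustiveHistory",
    "RcmDistance",
    "exhaustive_history",
    "lz_complexity",
    "concat_complexity",
    "rcm_distance",
]


@dataclass(frozen=True)
class ExhaustiveHistory:
    """The ordered LZ production components of a string.

    Concatenating ``components`` reproduces the parsed string exactly;
    ``complexity`` is the number of components.
    """

    components: tuple[str, ...]

    @property
    def complexity(self) -> int:
        return len(self.components)

    @property
    def string(self) -> str:
        return "".join(self.components)


@dataclass(frozen=True)
class RcmDistance:
    """Normalized LZ distance between two sequences X and Y.

    ``value = (c(XY) + c(YX) - c(X) - c(Y)) / ((c(XY) + c(YX)) / 2)``

    where c(XY) is the complexity of X followed by Y.  The value is symmetric
    in X and Y by construction and non-negative (parsing a concatenation never
    needs fewer steps than parsing its prefix alone).
    """

    value: float
    c_xy: int
    c_yx: int
    c_x: int
    c_y: int


def _longest_reproducible(s: str, start: int, limit: int) -> int:
    """Length of the longest prefix of ``s[start:]`` (capped at ``limit``)
    reproducible by copying from ``s[:start]`` with self-overlap allowed.

    ``s[start:start + m]`` is reproducible iff it occurs in ``s`` at a
    position whose copy window ends before the last of the ``m`` symbols,
    i.e. ``s.find(s[start:start + m], 0, start + m - 1) != -1``.
    Reproducibility is monotone in ``m`` (truncating a copy is a copy), so an
    exponential probe followed by bisection finds the maximum.
    """
    if start == 0 or limit == 0:
        return 0

    def ok(m: int) -> bool:
        return s.find(s[start : start + m], 0, start + m - 1) != -1

    if not ok(1):
        return 0
    # exponential growth phase
    lo = 1
    hi = 2
    while hi <= limit and ok(hi):
        lo = hi
        hi *= 2
    hi = min(hi, limit + 1)  # smallest known-bad (or limit+1)
    # invariant: ok(lo), not ok(hi) unless hi == limit + 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def exhaustive_history(s: str) -> ExhaustiveHistory:
    """Parse ``s`` into its LZ76 exhaustive production history.

    Deterministic; the empty string yields an empty history.
    """
    n = len(s)
    components: list[str] = []
    i = 0
    while i < n:
        m = _longest_reproducible(s, i, n - i)
        if i + m == n:
            # remainder fully reproducible: final component, no innovation
            components.append(s[i:])
            break
        components.append(s[i : i + m + 1])  # copied stretch + innovation
        i += m + 1
    return ExhaustiveHistory(tuple(components))


def lz_complexity(s: str) -> int:
    """Number of components in the exhaustive history of ``s``."""
    return exhaustive_history(s).complexity


def concat_complexity(x: str, y: str) -> int:
    """LZ complexity of ``x`` followed by ``y`` (both must be non-empty)."""
    if not x or not y:
        raise ValueError("concat_complexity requires non-empty operands")
    return lz_complexity(x + y)


def rcm_distance(
    x: str,
    y: str,
    *,
    c_x: int | None = None,
    c_y: int | None = None,
) -> RcmDistance:
    """Normalized LZ distance between sequences ``x`` and ``y``.

    ``c_x``/``c_y`` may be supplied to reuse cached per-sequence
    complexities; they must equal ``lz_complexity`` of the operand.
    """
    if not x or not y:
        raise ValueError("rcm_distance requires non-empty operands")
    cx = lz_complexity(x) if c_x is None else c_x
    cy = lz_complexity(y) if c_y is None else c_y
    cxy = concat_complexity(x, y)
    cyx = concat_complexity(y, x)
    value = (cxy + cyx - cx - cy) / ((cxy + cyx) / 2.0)
    return RcmDistance(value=value, c_xy=cxy, c_yx=cyx, c_x=cx, c_y=cy)
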