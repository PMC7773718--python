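"""Global pairwise DNA alignment with affine gap penalties.

The aligner is a Gotoh-style dynamic program over three state matrices
(match/mismatch, gap-in-b, gap-in-a).  A maximal gap run of length ``k``
costs ``gap_open + k * gap_extend``; both penalties are positive numbers.
Traceback is fully deterministic: on score ties a diagonal step is
preferred, then a gap in the second sequence, then a gap in the first,
and inside a gap state closing the gap is preferred over extending it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._dna import IUPAC_DNA, UNAMBIGUOUS, encode

_NEG = -1.0e30
_EPS = 1e-9


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and positive affine gap penalties."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class PairwiseAlignment:
    """A global alignment of two DNA sequences.

    ``compared_sites`` counts columns where both bases are unambiguous
    (A/C/G/T, no gap); ``variable_sites`` counts compared columns whose
    bases differ ("complete deletion" of gapped/ambiguous columns).
    """

    aligned_a: str
    aligned_b: str
    score: float
    compared_sites: int
    variable_sites: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")

    def __len__(self) -> int:
        return len(self.aligned_a)


def site_counts(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    """(compared, variable) column counts under complete deletion."""
    compared = 0
    variable = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            compared += 1
            if x != y:
                variable += 1
    return compared, variable


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jit
    n = a.size
    m = b.size
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b: consumes a
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a: consumes b
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + j * gap_extend)
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            M[i, j] = prev + s
            x = M[i - 1, j] - first
            if X[i - 1, j] - gap_extend > x:
                x = X[i - 1, j] - gap_extend
            if Y[i - 1, j] - first > x:
                x = Y[i - 1, j] - first
            X[i, j] = x
            y = M[i, j - 1] - first
            if Y[i, j - 1] - gap_extend > y:
                y = Y[i, j - 1] - gap_extend
            if X[i, j - 1] - first > y:
                y = X[i, j - 1] - first
            Y[i, j] = y
    return M, X, Y


def _traceback(a: str, b: str, M, X, Y, scheme: ScoringScheme) -> tuple[str, str]:
    i, j = len(a), len(b)
    first = scheme.gap_open + scheme.gap_extend
    # Final state priority: diagonal, gap-in-b, gap-in-a.
    state = max(("M", "X", "Y"), key=lambda s: ({"M": M, "X": X, "Y": Y}[s][i, j], s == "M", s == "X"))
    cols_a: list[str] = []
    cols_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            s = scheme.match if a[i - 1] == b[j - 1] else scheme.mismatch
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for st, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - target) < _EPS:
                    state = st
                    break
        elif state == "X":
            cols_a.append(a[i - 1])
            cols_b.append("-")
            here = X[i, j]
            i -= 1
            # Prefer closing the gap, then extending, then switching gaps.
            if abs(M[i, j] - first - here) < _EPS:
                state = "M"
            elif abs(X[i, j] - scheme.gap_extend - here) < _EPS:
                state = "X"
            else:
                state = "Y"
        else:
            cols_a.append("-")
            cols_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if abs(M[i, j] - first - here) < _EPS:
                state = "M"
            elif abs(Y[i, j] - scheme.gap_extend - here) < _EPS:
                state = "Y"
            else:
                state = "X"
    return "".join(reversed(cols_a)), "".join(reversed(cols_b))


def global_align(a: str, b: str, scoring: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two DNA sequences under affine gaps.

    Ambiguity codes are aligned literally (an ``N`` only scores a match
    against another ``N``) and are excluded from ``compared_sites``.
    """
    scheme = scoring or ScoringScheme()
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(f"sequence {name} has non-IUPAC characters: {sorted(bad)!r}")
    a = a.upper()
    b = b.upper()
    M, X, Y = _gotoh_fill(
        encode(a), encode(b), scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    score = max(M[-1, -1], X[-1, -1], Y[-1, -1])
    aligned_a, aligned_b = _traceback(a, b, M, X, Y, scheme)
    compared, variable = site_counts(aligned_a, aligned_b)
    return PairwiseAlignment(aligned_a, aligned_b, float(score), compared, variable)
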