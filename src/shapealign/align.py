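"""Global affine-gap alignment of SHAPE reactivity profiles (Gotoh).

Three matrices are filled over prefixes of profiles x and y:

* ``D[i, j]`` — best score of any alignment of x[:i] and y[:j];
* ``P[i, j]`` — best such alignment ending with x_i against a gap in y;
* ``Q[i, j]`` — best such alignment ending with y_j against a gap in x.

Recursions (GOP/GEP are the gap opening/extension penalties, both <= 0;
a gap of length L costs GOP + L*GEP, i.e. GOP + GEP on opening)::

    P[i, j] = max(P[i-1, j] + GEP,  D[i-1, j] + GOP + GEP)
    Q[i, j] = max(Q[i, j-1] + GEP,  D[i, j-1] + GOP + GEP)
    D[i, j] = max(s(x_i, y_j) + D[i-1, j-1],  P[i, j],  Q[i, j])

Initialization: D[0, 0] = 0, D[i, 0] = GOP + i*GEP, D[0, j] = GOP + j*GEP;
P[0, j] and Q[i, 0] hold a finite sentinel far below any achievable score.
Terminal gaps are penalized exactly like internal ones.

The traceback tracks which matrix the current cell was reached through, with
tie order diagonal > P (gap in y) > Q (gap in x); inside a gap run, closing
the gap is preferred over extending it when both are optimal.  This makes the
output deterministic.  ``exhaustive_align`` enumerates every global alignment
of tiny instances as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .scoring import AlignmentParams, column_score, score_matrix
from .types import ReactivityProfile, ShapeAlignError

__all__ = [
    "PairwiseAlignment",
    "gotoh_align",
    "exhaustive_align",
    "score_alignment",
]

#: Enumeration guard for the brute-force oracle.
EXHAUSTIVE_LIMIT = 16


class InconsistentAlignmentError(ShapeAlignError):
    """An alignment does not cover its profiles exactly once, in order."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """Ordered alignment columns plus the total score.

    ``columns`` is a tuple of ``(x_index | None, y_index | None)``; ``None``
    marks a gap.  No column is (None, None); each profile position appears
    exactly once, in increasing order.
    """

    columns: tuple
    score: float
    params: AlignmentParams

    def __post_init__(self) -> None:
        if any(ci is None and cj is None for ci, cj in self.columns):
            raise ValueError("alignment column with gaps on both sides")

    def __len__(self) -> int:
        return len(self.columns)

    def aligned_pairs(self, source: str = "predicted"):
        from .types import AlignedPairSet

        return AlignedPairSet.from_pairs(
            [(ci, cj) for ci, cj in self.columns if ci is not None and cj is not None],
            source,
        )


@njit(cache=True)
def _gotoh_fill(S, gop, gep, neg):  # pragma: no cover - exercised via gotoh_align
    m, n = S.shape
    D = np.empty((m + 1, n + 1))
    P = np.empty((m + 1, n + 1))
    Q = np.empty((m + 1, n + 1))
    opening = gop + gep
    D[0, 0] = 0.0
    P[0, 0] = neg
    Q[0, 0] = neg
    for i in range(1, m + 1):
        # sequential accumulation keeps bit-identity with a left-to-right re-sum
        D[i, 0] = (D[i - 1, 0] + opening) if i == 1 else (D[i - 1, 0] + gep)
        Q[i, 0] = neg
        P[i, 0] = max(P[i - 1, 0] + gep, D[i - 1, 0] + opening)
    for j in range(1, n + 1):
        D[0, j] = (D[0, j - 1] + opening) if j == 1 else (D[0, j - 1] + gep)
        P[0, j] = neg
        Q[0, j] = max(Q[0, j - 1] + gep, D[0, j - 1] + opening)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            p = max(P[i - 1, j] + gep, D[i - 1, j] + opening)
            q = max(Q[i, j - 1] + gep, D[i, j - 1] + opening)
            d = S[i - 1, j - 1] + D[i - 1, j - 1]
            if p > d:
                d = p
            if q > d:
                d = q
            P[i, j] = p
            Q[i, j] = q
            D[i, j] = d
    return D, P, Q


def _sentinel(S: np.ndarray, params: AlignmentParams, m: int, n: int) -> float:
    magnitude = float(np.max(np.abs(S))) if S.size else 1.0
    per_step = magnitude + abs(params.gop) + abs(params.gep) + 1.0
    return -4.0 * per_step * (m + n + 2)


def gotoh_align(
    px: ReactivityProfile, py: ReactivityProfile, params: AlignmentParams
) -> PairwiseAlignment:
    """Optimal global alignment of two reactivity profiles.

    Returns a :class:`PairwiseAlignment`; ties are broken deterministically
    (diagonal over gap-in-y over gap-in-x; gap closure over gap extension).
    """
    m, n = len(px), len(py)
    S = score_matrix(px, py, params)
    if m == 0 and n == 0:
        return PairwiseAlignment((), 0.0, params)
    neg = _sentinel(S, params, m, n)
    D, P, Q = _gotoh_fill(S, float(params.gop), float(params.gep), neg)
    opening = float(params.gop) + float(params.gep)

    columns: list = []
    i, j = m, n
    state = "D"
    while i > 0 and j > 0:
        if state == "D":
            diag = S[i - 1, j - 1] + D[i - 1, j - 1]
            if D[i, j] == diag:
                columns.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif D[i, j] == P[i, j]:
                state = "P"
            elif D[i, j] == Q[i, j]:
                state = "Q"
            else:  # pragma: no cover - DP construction guarantees a branch
                raise InconsistentAlignmentError("traceback found no valid branch")
        elif state == "P":
            columns.append((i - 1, None))
            if P[i, j] == D[i - 1, j] + opening:
                state = "D"
            elif P[i, j] == P[i - 1, j] + gep_of(params):
                state = "P"
            else:  # pragma: no cover
                raise InconsistentAlignmentError("traceback lost the P gap run")
            i -= 1
        else:  # state == "Q"
            columns.append((None, j - 1))
            if Q[i, j] == D[i, j - 1] + opening:
                state = "D"
            elif Q[i, j] == Q[i, j - 1] + gep_of(params):
                state = "Q"
            else:  # pragma: no cover
                raise InconsistentAlignmentError("traceback lost the Q gap run")
            j -= 1
    while i > 0:
        columns.append((i - 1, None))
        i -= 1
    while j > 0:
        columns.append((None, j - 1))
        j -= 1
    columns.reverse()
    return PairwiseAlignment(tuple(columns), float(D[m, n]), params)


def gep_of(params: AlignmentParams) -> float:
    return float(params.gep)


def _run_score(columns, px, py, params) -> float:
    """Column scores plus GOP + L*GEP for every maximal same-side gap run."""
    total = 0.0
    prev = "M"
    run_len = 0
    runs: list = []
    for ci, cj in columns:
        kind = "M" if (ci is not None and cj is not None) else ("P" if cj is None else "Q")
        if kind == "M":
            total += column_score(ci, cj, px, py, params)
            if run_len:
                runs.append(run_len)
                run_len = 0
        else:
            if kind != prev and run_len:
                runs.append(run_len)
                run_len = 0
            run_len += 1
        prev = kind
    if run_len:
        runs.append(run_len)
    for length in runs:
        total += params.gop + length * params.gep
    return total


def score_alignment(
    alignment: PairwiseAlignment,
    px: ReactivityProfile,
    py: ReactivityProfile,
    params: AlignmentParams | None = None,
) -> float:
    """Re-sum an alignment's score independently of the dynamic program.

    Column scores are added to GOP + L*GEP for every maximal gap run (a gap
    run switching sides counts as a new opening).  Raises
    :class:`InconsistentAlignmentError` if the alignment does not traverse
    both profiles exactly.
    """
    params = params or alignment.params
    xs = [ci for ci, _ in alignment.columns if ci is not None]
    ys = [cj for _, cj in alignment.columns if cj is not None]
    if xs != list(range(len(px))) or ys != list(range(len(py))):
        raise InconsistentAlignmentError(
            "alignment does not cover both profiles exactly once in order"
        )
    return _run_score(alignment.columns, px, py, params)


def exhaustive_align(
    px: ReactivityProfile, py: ReactivityProfile, params: AlignmentParams
):
    """Enumerate every global alignment of two tiny profiles.

    Returns ``(best_score, [column tuples of every optimal alignment])``.
    Scores every monotone matching by direct summation with affine gap
    costing; refuses instances with ``len(x) + len(y) > 16``.
    """
    m, n = len(px), len(py)
    if m + n > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive enumeration limited to len(x) + len(y) <= {EXHAUSTIVE_LIMIT}"
        )
    opening = params.gop + params.gep
    best: list = [-np.inf]
    optima: list = []

    def extend(i: int, j: int, score: float, prev: str, columns: tuple) -> None:
        if i == m and j == n:
            if score > best[0]:
                best[0] = score
                optima.clear()
                optima.append(columns)
            elif score == best[0]:
                optima.append(columns)
            return
        if i < m and j < n:
            s = column_score(i, j, px, py, params)
            extend(i + 1, j + 1, score + s, "M", columns + ((i, j),))
        if i < m:
            inc = opening if prev != "P" else params.gep
            extend(i + 1, j, score + inc, "P", columns + ((i, None),))
        if j < n:
            inc = opening if prev != "Q" else params.gep
            extend(i, j + 1, score + inc, "Q", columns + ((None, j),))

    extend(0, 0, 0.0, "M", ())
    return best[0], optima
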