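"""Full local alignment (SW2) of merged extended intervals, nucleus
detection, and result ranking.

The Smith-Waterman implementation is an affine-gap Gotoh dynamic program
(gap of length k costs ``gap_open + k * gap_extend``) with a deterministic
traceback: at equal score a cell prefers stopping (shorter local alignment),
then the diagonal move, then a gap in the reference, then a gap in the
query.  Ambiguous bases never match.

Each MEI is aligned as a query fragment against its reference window padded
by ``max_diagonal_drift`` on both sides, yielding a partial alignment (PA)
classified as genomic (GPA) or transposon (TPA) by the namespace of its
reference.  The *nucleus* of a PA spans from the first column of its
leftmost run of >=10 consecutive match columns to the last column of its
rightmost such run; it is the privileged region in junction disputes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from .extension import MergedExtendedInterval
from .params import AlignmentParams, DEFAULT_PARAMS
from .refdb import EncodedReference, reverse_complement
from .seeding import FORWARD, REVERSE

GPA = "GPA"
TPA = "TPA"

_PTR_STOP, _PTR_DIAG, _PTR_GAP_REF, _PTR_GAP_QUERY = 0, 1, 2, 3


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    neg = -1e18
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), neg, dtype=np.float64)  # gap in query row
    F = np.full((n + 1, m + 1), neg, dtype=np.float64)  # gap in reference row
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = opened from H
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] >= 0) else -mismatch
            diag = H[i - 1, j - 1] + s
            # priority at ties: stop > diagonal > gap-in-reference > gap-in-query
            val = 0.0
            ptr = _PTR_STOP
            if diag > val:
                val = diag
                ptr = _PTR_DIAG
            if F[i, j] > val:
                val = F[i, j]
                ptr = _PTR_GAP_REF
            if E[i, j] > val:
                val = E[i, j]
                ptr = _PTR_GAP_QUERY
            H[i, j] = val
            ptrH[i, j] = ptr
            if val > best:
                best = val
                bi = i
                bj = j
    return H, ptrH, ptrE, ptrF, best, bi, bj


@dataclass
class LocalAlignment:
    """A scored gapped local alignment of two raw strings (1-based spans)."""

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


def _codes_for_dp(s: str, sentinel: int) -> np.ndarray:
    """Integer codes for the DP; ambiguous bases get a negative sentinel so
    they can never match (distinct sentinels per side)."""
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([lut.get(c.upper(), sentinel) for c in s], dtype=np.int64)


def smith_waterman(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> LocalAlignment:
    """Best-scoring affine-gap local alignment of ``a`` (query) vs ``b``.

    Deterministic: ties in the best cell go to the smallest (row, column);
    ties within a cell follow the fixed move priority.  Two strings with no
    common letter yield the empty alignment with score 0.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    ca = _codes_for_dp(a, -1)
    cb = _codes_for_dp(b, -2)
    H, ptrH, ptrE, ptrF, best, bi, bj = _gotoh_fill(
        ca, cb, params.match, params.mismatch_penalty, params.gap_open, params.gap_extend
    )
    if best <= 0:
        return LocalAlignment("", "", 0.0, 0, 0, 0, 0)
    # earliest best cell in row-major order for determinism
    flat = np.flatnonzero(H == best)
    bi, bj = divmod(int(flat[0]), H.shape[1])
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = bi, bj
    while i > 0 and j > 0 and ptrH[i, j] != _PTR_STOP:
        move = ptrH[i, j]
        if move == _PTR_DIAG:
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == _PTR_GAP_REF:  # gap in reference row: consume query
            while True:
                cols_a.append(a[i - 1])
                cols_b.append("-")
                opened = ptrF[i, j] == 1
                i -= 1
                if opened:
                    break
        else:  # gap in query row: consume reference
            while True:
                cols_a.append("-")
                cols_b.append(b[j - 1])
                opened = ptrE[i, j] == 1
                j -= 1
                if opened:
                    break
    return LocalAlignment(
        "".join(reversed(cols_a)),
        "".join(reversed(cols_b)),
        float(best),
        i + 1,
        bi,
        j + 1,
        bj,
    )


def score_alignment(aligned_a: str, aligned_b: str, params: AlignmentParams) -> float:
    """Re-score a gapped alignment pair under ``params`` (oracle hook)."""
    total = 0.0
    gap_run = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            gap_run += 1
            continue
        if gap_run:
            total -= params.gap_open + gap_run * params.gap_extend
            gap_run = 0
        if x.upper() == y.upper() and x.upper() in "ACGT":
            total += params.match
        else:
            total -= params.mismatch_penalty
    if gap_run:
        total -= params.gap_open + gap_run * params.gap_extend
    return total


@dataclass
class PartialAlignment:
    """A scored local alignment of a query fragment against one reference.

    Query coordinates are 1-based on the *forward* query; the aligned pair
    is stored so that the query row reads left-to-right along the forward
    query for both strands.  For reverse-strand PAs the reference
    coordinates therefore decrease along columns, from ``ref_end`` down to
    ``ref_start``.
    """

    kind: str                 # GPA | TPA
    ref_name: str
    namespace: str
    strand: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    aligned_query: str
    aligned_ref: str
    score: float
    nucleus: tuple[int, int] | None = None  # 1-based column span

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned rows must have equal column counts")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    def match_columns(self) -> np.ndarray:
        q = np.frombuffer(self.aligned_query.upper().encode(), dtype="S1")
        r = np.frombuffer(self.aligned_ref.upper().encode(), dtype="S1")
        ok = np.isin(q, np.array([b"A", b"C", b"G", b"T"]))
        return (q == r) & ok

    def query_pos_at_col(self, col: int) -> int:
        """Forward-query position of the base in 1-based column ``col``."""
        consumed = sum(1 for c in self.aligned_query[: col - 1] if c != "-")
        return self.query_start + consumed

    def ref_coord_at_col(self, col: int) -> int:
        consumed = sum(1 for c in self.aligned_ref[: col - 1] if c != "-")
        if self.strand == FORWARD:
            return self.ref_start + consumed
        return self.ref_end - consumed

    def terminal_ref_coords(self) -> tuple[int, int]:
        """Reference coordinates at the leftmost / rightmost columns."""
        if self.strand == FORWARD:
            return self.ref_start, self.ref_end
        return self.ref_end, self.ref_start

    def nucleus_query_span(self) -> tuple[int, int] | None:
        if self.nucleus is None:
            return None
        return (
            self.query_pos_at_col(self.nucleus[0]),
            self.query_pos_at_col(self.nucleus[1]),
        )

    def nucleus_length(self) -> int:
        return 0 if self.nucleus is None else self.nucleus[1] - self.nucleus[0] + 1


def find_nucleus(pa: PartialAlignment, min_run: int = 10) -> tuple[int, int] | None:
    """Nucleus column span: from the first column of the leftmost run of
    ``>= min_run`` consecutive match columns to the last column of the
    rightmost such run; absent when no qualifying run exists."""
    matches = pa.match_columns()
    runs = _match_runs(matches, min_run)
    if not runs:
        return None
    return runs[0][0], runs[-1][1]


def _match_runs(matches: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(matches):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_run:
                runs.append((start + 1, i))
            start = None
    if start is not None and len(matches) - start >= min_run:
        runs.append((start + 1, len(matches)))
    return runs


def align_fragment(
    oriented_fragment: str,
    frag_query_start: int,       # oriented-query start of the fragment
    ref: EncodedReference,
    win_start: int,
    win_end: int,
    strand: str,
    query_length: int,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> PartialAlignment | None:
    """Locally align an oriented query fragment against ref[win_start..win_end]
    and emit a PA in forward-query coordinates (or None if nothing aligns)."""
    win_start = max(1, win_start)
    win_end = min(ref.length, win_end)
    window = ref.sequence(win_start, win_end)
    la = smith_waterman(oriented_fragment, window, params)
    if la.is_empty:
        return None
    oq_start = frag_query_start + la.a_start - 1
    oq_end = frag_query_start + la.a_end - 1
    rs = win_start + la.b_start - 1
    re_ = win_start + la.b_end - 1
    if strand == FORWARD:
        q_start, q_end = oq_start, oq_end
        aq, ar = la.aligned_a, la.aligned_b
    else:
        q_start = query_length - oq_end + 1
        q_end = query_length - oq_start + 1
        aq = reverse_complement(la.aligned_a)
        ar = reverse_complement(la.aligned_b)
    kind = TPA if ref.namespace == "transposon" else GPA
    pa = PartialAlignment(
        kind, ref.name, ref.namespace, strand,
        q_start, q_end, rs, re_, aq, ar, la.score,
    )
    pa.nucleus = find_nucleus(pa, params.nucleus_min_run)
    return pa


def align_mei(
    mei: MergedExtendedInterval,
    query: str,
    ref: EncodedReference,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> PartialAlignment | None:
    """SW2: full local alignment of the MEI's query fragment against its
    reference window padded by ``max_diagonal_drift`` on each side."""
    oriented = query if mei.strand == FORWARD else reverse_complement(query)
    fragment = oriented[mei.query_start - 1 : mei.query_end]
    return align_fragment(
        fragment,
        mei.query_start,
        ref,
        mei.ref_start - params.max_diagonal_drift,
        mei.ref_end + params.max_diagonal_drift,
        mei.strand,
        len(query),
        params,
    )


def rank_results(items: Sequence, key: str = "score") -> list:
    """Stable sort of PAs / final alignments for reporting.

    ``score``: descending score, ties by (ref_name, ref_start) ascending;
    ``location``: by reference then coordinate; ``coordinate``: by
    coordinate then reference.
    """
    def _ref_name(x):
        return getattr(x, "ref_name", "")

    def _ref_start(x):
        return getattr(x, "ref_start", 0)

    if key == "score":
        return sorted(items, key=lambda x: (-x.score, _ref_name(x), _ref_start(x)))
    if key == "location":
        return sorted(items, key=lambda x: (_ref_name(x), _ref_start(x), -x.score))
    if key == "coordinate":
        return sorted(items, key=lambda x: (_ref_start(x), _ref_name(x), -x.score))
    raise ValueError(f"unknown sort key {key!r}")
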