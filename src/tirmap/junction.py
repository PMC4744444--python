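"""Joining of partial alignments into final alignments, SW3 border
re-alignment, TGN calling, orientation classification and the bonus.

The composite query (transposon-genome junction read) is covered by a chain
of partial alignments.  Chains are enumerated over compatible PAs; query
overlaps between neighbours are resolved by the joining rules (a nucleus is
privileged over a tail; nucleus-nucleus overlaps up to 40 % of each nucleus
go to the transposon side; larger ones refuse the join), unaligned query
columns between neighbours are assigned to the side whose border is not
pinned at a TIR terminus, and every trimmed fragment is re-aligned (SW3)
against its reference window elongated by the next 10 reference nucleotides
on each side.  That re-alignment is what lets a terminal genomic nucleotide
(TGN) sitting beyond a junction-proximal SNP or indel re-enter the final
alignment as a terminal match.

The TGN reported for an insertion is the genomic reference coordinate at
the first genomic column after the border — shared (overlapped) columns
having been assigned to the transposon — provided the transposon side of
the border ends at a TIR terminus (construct coordinate 1 or L).  A border
between two transposon references is a self-insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import (
    GPA,
    TPA,
    PartialAlignment,
    align_fragment,
    score_alignment,
)
from .params import AlignmentParams, DEFAULT_PARAMS
from .refdb import EncodedReference, Feature, ReferenceDatabase, reverse_complement
from .seeding import FORWARD

SW3_LATERAL = 10  # reference elongation (nt) on each side during SW3


@dataclass
class Border:
    """Junction between two adjacent segments of a final alignment."""

    left_index: int
    right_index: int
    left_query_end: int
    right_query_start: int
    left_kind: str
    right_kind: str
    tir_terminal: int | None = None   # construct terminus coordinate at the border
    terminal_side: str | None = None  # 'left' | 'right' (which side is at a terminus)

    @property
    def is_transposon_genome(self) -> bool:
        return {self.left_kind, self.right_kind} == {TPA, GPA}

    @property
    def is_transposon_transposon(self) -> bool:
        return self.left_kind == TPA and self.right_kind == TPA


@dataclass
class FinalAlignment:
    segments: list[PartialAlignment]
    borders: list[Border]
    sw_score: float                  # sum of segment SW scores
    total_score: float               # sw_score + bonus when applied
    bonus_applied: bool = False

    @property
    def score(self) -> float:
        return self.total_score

    @property
    def ref_name(self) -> str:
        return self.segments[0].ref_name

    @property
    def ref_start(self) -> int:
        return min(s.ref_start for s in self.segments)

    def coverage(self, query_length: int) -> float:
        covered = sum(s.query_end - s.query_start + 1 for s in self.segments)
        return covered / query_length

    def signature(self) -> tuple:
        return tuple(
            (s.kind, s.ref_name, s.strand, s.query_start, s.query_end, s.ref_start, s.ref_end)
            for s in self.segments
        )


@dataclass
class InsertionCall:
    call_kind: str                    # genomic_insertion | self_insertion | genomic_only | transposon_only
    query_id: str = ""
    ref_name: str | None = None
    tgn_coordinate: int | None = None
    tir_terminal_coordinate: int | None = None
    transposon_name: str | None = None
    orientation: str | None = None    # type_I | type_II
    sequenced_end: str | None = None  # five_prime | three_prime
    genomic_strand: str | None = None
    score: float = 0.0
    bonus_applied: bool = False
    low_confidence: bool = False
    affected_features: list[str] = field(default_factory=list)
    left_flank: str | None = None
    right_flank: str | None = None
    warnings: list[str] = field(default_factory=list)


# -- overlap resolution ----------------------------------------------------


def _col_for_query_end(pa: PartialAlignment, b: int) -> int:
    """Largest 1-based column index whose consumed query bases stay within
    forward-query position <= b (0 when b precedes the PA)."""
    target = b - pa.query_start + 1
    if target <= 0:
        return 0
    consumed = 0
    last = 0
    for c, ch in enumerate(pa.aligned_query, start=1):
        if ch != "-":
            consumed += 1
            if consumed > target:
                break
        last = c
    return last


def _keep_score(pa: PartialAlignment, q_from: int, q_to: int, params: AlignmentParams) -> float:
    """Score of the alignment columns whose query bases lie in [q_from, q_to]."""
    hi = _col_for_query_end(pa, q_to)
    lo = _col_for_query_end(pa, q_from - 1)
    if hi <= lo:
        return 0.0
    return score_alignment(pa.aligned_query[lo:hi], pa.aligned_ref[lo:hi], params)


def resolve_overlap(
    left: PartialAlignment,
    right: PartialAlignment,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> int | None:
    """Resolve a query overlap between two PAs into a boundary position.

    Returns ``b`` such that the left PA keeps query positions ``<= b`` and
    the right one ``>= b+1``, or ``None`` when the pair refuses to join
    (nucleus-nucleus overlap exceeding 40 % of either nucleus).

    Rules: a nucleus may not be invaded by the partner's tail (the tail is
    trimmed back to the nucleus boundary); residual tail-tail overlap is
    split at the query position maximising the summed kept-column scores
    (ties to the leftmost); nucleus-nucleus overlaps within the 40 % limit
    are assigned whole to the TPA (same-kind pairs: to the higher-scoring
    PA).
    """
    if right.query_start > left.query_end:
        raise ValueError("PAs do not overlap on the query")
    lo = max(right.query_start - 1, left.query_start)
    hi = min(left.query_end, right.query_end - 1)
    if lo > hi:
        return None
    ln = left.nucleus_query_span()
    rn = right.nucleus_query_span()
    # a tail may not keep columns inside the partner's nucleus
    if ln is not None and ln[1] >= right.query_start:
        lo = max(lo, ln[1])
    if rn is not None and rn[0] <= left.query_end:
        hi = min(hi, rn[0] - 1)
    if lo <= hi:
        if lo == hi:
            return lo
        best_b, best_s = lo, None
        for b in range(lo, hi + 1):
            s = _keep_score(left, left.query_start, b, params) + _keep_score(
                right, b + 1, right.query_end, params
            )
            if best_s is None or s > best_s:
                best_b, best_s = b, s
        return best_b
    # nucleus-nucleus dispute
    assert ln is not None and rn is not None
    overlap = ln[1] - rn[0] + 1
    n1 = ln[1] - ln[0] + 1
    n2 = rn[1] - rn[0] + 1
    frac = params.nucleus_max_overlap_frac
    if overlap > frac * n1 or overlap > frac * n2:
        return None
    if left.kind == right.kind:
        winner_left = left.score >= right.score
    else:
        winner_left = left.kind == TPA
    b = ln[1] if winner_left else rn[0] - 1
    if not (left.query_start <= b <= right.query_end - 1):
        return None
    return b


# -- SW3 -------------------------------------------------------------------


def sw3_realign(
    pa: PartialAlignment,
    query: str,
    ref: EncodedReference,
    params: AlignmentParams = DEFAULT_PARAMS,
    query_range: tuple[int, int] | None = None,
) -> PartialAlignment | None:
    """Re-align a (possibly trimmed/expanded) query fragment of ``pa``
    against its reference window elongated by the next ``SW3_LATERAL``
    reference nucleotides on each side, clamped at the reference ends."""
    qs, qe = query_range if query_range is not None else (pa.query_start, pa.query_end)
    if qs > qe:
        return None
    if pa.strand == FORWARD:
        fragment = query[qs - 1 : qe]
        frag_start = qs
    else:
        n = len(query)
        oq_start = n - qe + 1
        fragment = reverse_complement(query[qs - 1 : qe])
        frag_start = oq_start
    return align_fragment(
        fragment,
        frag_start,
        ref,
        pa.ref_start - SW3_LATERAL,
        pa.ref_end + SW3_LATERAL,
        pa.strand,
        len(query),
        params,
    )


# -- chain assembly --------------------------------------------------------


def _border_end_coord(pa: PartialAlignment, side: str) -> int:
    """Aligned reference coordinate at the border-facing end of a segment
    (side='right' means the segment's rightmost query column)."""
    left_coord, right_coord = pa.terminal_ref_coords()
    return right_coord if side == "right" else left_coord


def _at_tir_terminus(pa: PartialAlignment, side: str, db: ReferenceDatabase) -> int | None:
    if pa.kind != TPA:
        return None
    coord = _border_end_coord(pa, side)
    length = db.get(pa.ref_name, pa.namespace).length
    if coord in (1, length):
        return coord
    return None


def _enumerate_chains(
    pas: list[PartialAlignment],
    params: AlignmentParams,
    overlap_cache: dict[tuple[int, int], int | None],
) -> list[list[PartialAlignment]]:
    """All orderly chains of compatible PAs (bounded gaps, resolvable
    overlaps), capped for tractability.

    Only segments of at least ``min_chain_segment`` query nt may join a
    multi-segment chain: very short chance matches would otherwise be
    spliced in purely to manufacture extra (bonus-carrying) borders.
    Every PA still forms its own single-segment candidate.
    """

    def resolved(i: int, j: int) -> int | None:
        key = (i, j)
        if key not in overlap_cache:
            overlap_cache[key] = resolve_overlap(pas[i], pas[j], params)
        return overlap_cache[key]

    chainable = [
        i
        for i in range(len(pas))
        if pas[i].query_end - pas[i].query_start + 1 >= params.min_chain_segment
    ]
    order = sorted(chainable, key=lambda i: (pas[i].query_start, pas[i].query_end))
    chains: list[list[int]] = [[i] for i in range(len(pas))]
    budget = [4000]

    def extend(chain: list[int]) -> None:
        if budget[0] <= 0:
            return
        budget[0] -= 1
        if len(chain) > 1:
            chains.append(list(chain))
        last = pas[chain[-1]]
        for j in order:
            if budget[0] <= 0 or j in chain or len(chain) >= 6:
                continue
            nxt = pas[j]
            if nxt.query_start <= last.query_start or nxt.query_end <= last.query_end:
                continue  # keep strict left-to-right progress
            if nxt.query_start > last.query_end + params.max_unaligned_gap + 1:
                continue
            if nxt.query_start <= last.query_end:
                if resolved(chain[-1], j) is None:
                    continue
            chain.append(j)
            extend(chain)
            chain.pop()

    for i in order:
        extend([i])
    return [[pas[i] for i in ch] for ch in chains]


def _chain_to_final(
    chain: list[PartialAlignment],
    query: str,
    db: ReferenceDatabase,
    params: AlignmentParams,
    overlap_cache: dict | None = None,
    sw3_cache: dict | None = None,
    chain_ids: list[int] | None = None,
) -> FinalAlignment | None:
    if len(chain) == 1:
        pa = chain[0]
        return FinalAlignment([pa], [], pa.score, pa.score)
    # 1. boundaries between neighbours (query positions)
    bounds: list[int] = []
    prev_b = 0
    for k, (left, right) in enumerate(zip(chain, chain[1:])):
        if right.query_start <= left.query_end:
            if overlap_cache is not None and chain_ids is not None:
                key = (chain_ids[k], chain_ids[k + 1])
                if key not in overlap_cache:
                    overlap_cache[key] = resolve_overlap(left, right, params)
                b = overlap_cache[key]
            else:
                b = resolve_overlap(left, right, params)
            if b is None or b <= prev_b:
                return None
        else:
            gap = right.query_start - left.query_end - 1
            if gap == 0:
                b = left.query_end
            else:
                left_pinned = _at_tir_terminus(left, "right", db) is not None
                right_pinned = _at_tir_terminus(right, "left", db) is not None
                if left_pinned and not right_pinned:
                    b = left.query_end            # whole gap goes right
                elif right_pinned and not left_pinned:
                    b = right.query_start - 1     # whole gap goes left
                else:
                    b = left.query_end + gap // 2
        bounds.append(b)
        prev_b = b
    # 2. SW3 re-alignment of each trimmed fragment
    segments: list[PartialAlignment] = []
    for i, pa in enumerate(chain):
        qs = pa.query_start if i == 0 else bounds[i - 1] + 1
        qe = pa.query_end if i == len(chain) - 1 else bounds[i]
        if sw3_cache is not None and chain_ids is not None:
            key = (chain_ids[i], qs, qe)
            if key not in sw3_cache:
                ref = db.get(pa.ref_name, pa.namespace)
                sw3_cache[key] = sw3_realign(pa, query, ref, params, (qs, qe))
            new = sw3_cache[key]
        else:
            ref = db.get(pa.ref_name, pa.namespace)
            new = sw3_realign(pa, query, ref, params, (qs, qe))
        if new is None:
            return None
        segments.append(new)
    for a, b2 in zip(segments, segments[1:]):
        if b2.query_start <= a.query_end:
            return None
    # 3. borders and score
    borders: list[Border] = []
    for i, (left, right) in enumerate(zip(segments, segments[1:])):
        border = Border(
            i, i + 1, left.query_end, right.query_start, left.kind, right.kind
        )
        t_left = _at_tir_terminus(left, "right", db)
        t_right = _at_tir_terminus(right, "left", db)
        if t_left is not None:
            border.tir_terminal, border.terminal_side = t_left, "left"
        elif t_right is not None:
            border.tir_terminal, border.terminal_side = t_right, "right"
        borders.append(border)
    sw = sum(s.score for s in segments)
    return FinalAlignment(segments, borders, sw, sw)


def apply_bonus(fa: FinalAlignment, params: AlignmentParams = DEFAULT_PARAMS) -> FinalAlignment:
    """Add the cumulative bonus: +bonus per transposon-genome border when
    enabled; transposon-transposon (self-insertion) borders never qualify."""
    n_tg = sum(1 for b in fa.borders if b.is_transposon_genome)
    if not params.bonus_enabled or n_tg == 0:
        return FinalAlignment(fa.segments, fa.borders, fa.sw_score, fa.sw_score, False)
    return FinalAlignment(
        fa.segments, fa.borders, fa.sw_score, fa.sw_score + params.bonus * n_tg, True
    )


def assemble_final(
    pas: list[PartialAlignment],
    query: str,
    db: ReferenceDatabase,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[FinalAlignment]:
    """Enumerate, re-align (SW3) and rank candidate final alignments.

    Chains are scored as the sum of their segments' SW scores, plus the
    bonus per transposon-genome border when enabled.  Returns the ranked,
    deduplicated list (best first); empty when no PA exists.
    """
    if not pas:
        return []
    kept = sorted(pas, key=lambda p: (-p.score, p.ref_name, p.ref_start))
    kept = [p for p in kept if p.score >= params.min_pa_score] or kept[:1]
    kept = kept[: params.max_candidates]
    overlap_cache: dict[tuple[int, int], int | None] = {}
    sw3_cache: dict[tuple[int, int, int], PartialAlignment | None] = {}
    ids = {id(p): i for i, p in enumerate(kept)}
    finals: dict[tuple, FinalAlignment] = {}
    for chain in _enumerate_chains(kept, params, overlap_cache):
        fa = _chain_to_final(
            chain, query, db, params,
            overlap_cache, sw3_cache, [ids[id(p)] for p in chain],
        )
        if fa is None:
            continue
        fa = apply_bonus(fa, params)
        sig = fa.signature()
        old = finals.get(sig)
        if old is None or fa.total_score > old.total_score:
            finals[sig] = fa
    ranked = sorted(
        finals.values(),
        key=lambda f: (-f.total_score, -f.coverage(len(query)), f.signature()),
    )
    return ranked


# -- insertion calling -----------------------------------------------------


def classify_orientation(fa: FinalAlignment) -> tuple[str, str]:
    """Orientation (type I/II) and sequenced transposon end for a final
    alignment with exactly one transposon-genome border at a TIR terminus.

    Type I means the transposon and genomic strands run in the same sense
    (the two arrows point the same way); the sequenced end follows from
    which construct terminus sits at the border (1 -> 5', L -> 3').
    """
    qualified = [
        b for b in fa.borders if b.is_transposon_genome and b.tir_terminal is not None
    ]
    if len(qualified) != 1:
        raise ValueError("orientation requires exactly one TIR-terminus transposon-genome border")
    b = qualified[0]
    tp = fa.segments[b.left_index if b.terminal_side == "left" else b.right_index]
    gn = fa.segments[b.right_index if b.terminal_side == "left" else b.left_index]
    orientation = "type_I" if tp.strand == gn.strand else "type_II"
    end = "five_prime" if b.tir_terminal == 1 else "three_prime"
    return orientation, end


def call_insertion(
    fa: FinalAlignment,
    db: ReferenceDatabase,
    query_id: str = "",
) -> InsertionCall:
    """Derive the insertion call (TGN coordinate and metadata) from the best
    final alignment."""
    kinds = {s.kind for s in fa.segments}
    tg_borders = [b for b in fa.borders if b.is_transposon_genome]
    tt_borders = [
        b for b in fa.borders if b.is_transposon_transposon and b.tir_terminal is not None
    ]
    qualified = [b for b in tg_borders if b.tir_terminal is not None]

    if qualified or tg_borders:
        low_conf = not qualified
        border = (qualified or tg_borders)[0]
        if border.terminal_side == "right":
            tp_i, gn_i = border.right_index, border.left_index
        elif border.terminal_side == "left":
            tp_i, gn_i = border.left_index, border.right_index
        else:  # no terminus at all: transposon side is whichever is the TPA
            tp_i = border.left_index if border.left_kind == TPA else border.right_index
            gn_i = border.right_index if tp_i == border.left_index else border.left_index
        tp, gn = fa.segments[tp_i], fa.segments[gn_i]
        # first genomic column adjacent to the border
        gn_col = gn.n_columns if gn_i < tp_i else 1
        tgn = gn.ref_coord_at_col(gn_col)
        call = InsertionCall(
            "genomic_insertion",
            query_id,
            ref_name=gn.ref_name,
            tgn_coordinate=tgn,
            tir_terminal_coordinate=border.tir_terminal,
            transposon_name=tp.ref_name,
            genomic_strand=gn.strand,
            score=fa.total_score,
            bonus_applied=fa.bonus_applied,
            low_confidence=low_conf,
        )
        single_qualified = [
            b for b in fa.borders if b.is_transposon_genome and b.tir_terminal is not None
        ]
        if len(single_qualified) == 1:
            call.orientation, call.sequenced_end = classify_orientation(fa)
        _annotate(call, db, gn.ref_name, gn.namespace, tgn)
        return call

    if tt_borders:
        border = tt_borders[0]
        # target side = the partner of the terminus-pinned TPA
        tgt_i = border.right_index if border.terminal_side == "left" else border.left_index
        tgt = fa.segments[tgt_i]
        tgn = tgt.ref_coord_at_col(1 if border.terminal_side == "left" else tgt.n_columns)
        call = InsertionCall(
            "self_insertion",
            query_id,
            ref_name=tgt.ref_name,
            tgn_coordinate=tgn,
            tir_terminal_coordinate=border.tir_terminal,
            transposon_name=fa.segments[
                border.left_index if border.terminal_side == "left" else border.right_index
            ].ref_name,
            score=fa.total_score,
            bonus_applied=fa.bonus_applied,
        )
        _annotate(call, db, tgt.ref_name, tgt.namespace, tgn)
        return call

    kind = "transposon_only" if kinds == {TPA} else "genomic_only"
    seg = fa.segments[0]
    call = InsertionCall(
        kind,
        query_id,
        ref_name=seg.ref_name,
        score=fa.total_score,
        bonus_applied=fa.bonus_applied,
        genomic_strand=seg.strand,
    )
    return call


def _annotate(
    call: InsertionCall, db: ReferenceDatabase, ref_name: str, namespace: str, coord: int
) -> None:
    track = db.annotations_for(ref_name, namespace)
    if track is None:
        return
    call.affected_features = [f.label for f in track.overlapping(coord)]
    left, right = track.flanking(coord)
    call.left_flank = left.label if left else None
    call.right_flank = right.label if right else None
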