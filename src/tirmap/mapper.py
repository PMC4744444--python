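"""End-to-end mapping facade: query in, ranked final alignments and an
insertion call out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment import PartialAlignment, align_mei, rank_results
from .extension import extend_interval, merge_extended
from .junction import FinalAlignment, InsertionCall, assemble_final, call_insertion
from .params import AlignmentParams, DEFAULT_PARAMS
from .refdb import ReferenceDatabase, reverse_complement
from .seeding import FORWARD, K, merge_hits, scan_query

log = logging.getLogger("tirmap")


@dataclass
class MappingResult:
    query_id: str
    query: str
    partial_alignments: list[PartialAlignment] = field(default_factory=list)
    final_alignments: list[FinalAlignment] = field(default_factory=list)
    call: InsertionCall | None = None
    unmappable: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def best(self) -> FinalAlignment | None:
        return self.final_alignments[0] if self.final_alignments else None


class InsertionMapper:
    """Maps junction queries against a reference database.

    Runs the full heuristic: decamer seeding on both strands, gliding-window
    extension, MEI merging, full local alignment (SW2), chain assembly with
    border re-alignment (SW3), bonus application and insertion calling.
    """

    def __init__(self, db: ReferenceDatabase, params: AlignmentParams = DEFAULT_PARAMS):
        self.db = db
        self.params = params

    def partial_alignments(self, query: str) -> list[PartialAlignment]:
        hits = scan_query(query, self.db)
        ais = merge_hits(hits)
        log.debug("seeding: %d hits -> %d association intervals", len(hits), len(ais))
        eis = []
        for ai in ais:
            ref = self.db.get(ai.ref_name, ai.namespace)
            oriented = query if ai.strand == FORWARD else reverse_complement(query)
            eis.append(extend_interval(ai, oriented, ref.sequence(), self.params))
        meis = merge_extended(eis, self.params)
        log.debug("extension: %d EIs -> %d MEIs", len(eis), len(meis))
        pas: dict[tuple, PartialAlignment] = {}
        for mei in meis:
            ref = self.db.get(mei.ref_name, mei.namespace)
            pa = align_mei(mei, query, ref, self.params)
            if pa is None:
                continue
            sig = (pa.kind, pa.ref_name, pa.strand, pa.query_start, pa.query_end,
                   pa.ref_start, pa.ref_end)
            old = pas.get(sig)
            if old is None or pa.score > old.score:
                pas[sig] = pa
        return rank_results(list(pas.values()), "score")

    def map_query(self, query: str, query_id: str = "query") -> MappingResult:
        query = query.strip().upper()
        res = MappingResult(query_id, query)
        if len(query) < K:
            res.unmappable = True
            res.warnings.append(f"query shorter than {K} nt")
            return res
        res.partial_alignments = self.partial_alignments(query)
        if not res.partial_alignments:
            res.unmappable = True
            res.warnings.append("no partial alignment found for any reference")
            return res
        res.final_alignments = assemble_final(
            res.partial_alignments, query, self.db, self.params
        )
        if not res.final_alignments:
            res.unmappable = True
            res.warnings.append("no joinable chain of partial alignments")
            return res
        if self.params.bonus_enabled:
            plain = assemble_final(
                res.partial_alignments, query, self.db,
                self.params.with_(bonus_enabled=False),
            )
            if plain and plain[0].signature() != res.final_alignments[0].signature():
                res.warnings.append(
                    "bonus changed the top-ranked alignment; for suspected "
                    "self-insertions re-run with the bonus disabled"
                )
        res.call = call_insertion(res.final_alignments[0], self.db, query_id)
        res.call.warnings = list(res.warnings)
        return res


# -- report rendering ------------------------------------------------------


def render_text(res: MappingResult, max_alignments: int = 3, width: int = 60) -> str:
    """Human-readable report: call summary plus two-row gapped alignments
    with segment kind markers and coordinates."""
    lines = [f"## query {res.query_id} ({len(res.query)} nt)"]
    if res.unmappable:
        lines.append("UNMAPPABLE: " + "; ".join(res.warnings))
        return "\n".join(lines) + "\n"
    c = res.call
    assert c is not None
    lines.append(
        f"call: {c.call_kind}  ref={c.ref_name}  TGN={c.tgn_coordinate}  "
        f"TIR_terminus={c.tir_terminal_coordinate}  orientation={c.orientation}  "
        f"end={c.sequenced_end}  score={c.score:.0f}"
        + ("  [bonus]" if c.bonus_applied else "")
        + ("  [low-confidence]" if c.low_confidence else "")
    )
    if c.affected_features:
        lines.append(f"affected: {', '.join(c.affected_features)}")
    if c.left_flank or c.right_flank:
        lines.append(f"flanks: {c.left_flank} | {c.right_flank}")
    for w in res.warnings:
        lines.append(f"warning: {w}")
    for rank, fa in enumerate(res.final_alignments[:max_alignments], 1):
        lines.append(
            f"# alignment {rank}: score={fa.total_score:.0f} "
            f"(SW {fa.sw_score:.0f}{', bonus' if fa.bonus_applied else ''}), "
            f"{len(fa.segments)} segment(s)"
        )
        for seg in fa.segments:
            arrow = "->" if seg.strand == FORWARD else "<-"
            lines.append(
                f"  [{seg.kind}] {seg.ref_name} {arrow} query "
                f"{seg.query_start}..{seg.query_end} ref {seg.ref_start}..{seg.ref_end} "
                f"score {seg.score:.0f}"
            )
            for off in range(0, seg.n_columns, width):
                lines.append("    q: " + seg.aligned_query[off : off + width])
                lines.append("    r: " + seg.aligned_ref[off : off + width])
    return "\n".join(lines) + "\n"


def call_to_dict(res: MappingResult) -> dict:
    """Machine-readable (JSON/TSV-ready) record for one query."""
    c = res.call
    base = {
        "query_id": res.query_id,
        "query_length": len(res.query),
        "unmappable": res.unmappable,
    }
    if c is None:
        base.update({"call_kind": None})
        return base
    base.update(
        {
            "call_kind": c.call_kind,
            "ref_name": c.ref_name,
            "tgn_coordinate": c.tgn_coordinate,
            "tir_terminal_coordinate": c.tir_terminal_coordinate,
            "transposon_name": c.transposon_name,
            "orientation": c.orientation,
            "sequenced_end": c.sequenced_end,
            "genomic_strand": c.genomic_strand,
            "score": c.score,
            "bonus_applied": c.bonus_applied,
            "low_confidence": c.low_confidence,
            "affected_features": c.affected_features,
            "left_flank": c.left_flank,
            "right_flank": c.right_flank,
            "warnings": c.warnings,
        }
    )
    return base
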