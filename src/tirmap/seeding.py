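"""Decamer seeding: scan a query against the hash indexes and merge the
resulting basic intervals (BIs) into gap-free association intervals.

Both strands are searched.  Reverse-strand hits are found by scanning the
reverse complement of the query; all downstream per-hit coordinates are kept
in *oriented-query* space (i.e. coordinates on the reverse-complemented
query for reverse-strand hits), which preserves the simple diagonal
``ref_start - query_start`` bookkeeping and the literal exact-match
invariant ``oriented_query[qs..qe] == ref[rs..re]``.  Conversion back to
forward-query coordinates happens when partial alignments are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .refdb import K, ReferenceDatabase, query_window_keys, reverse_complement

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class BasicIntervalHit:
    """A single decamer match (BI) between query and reference.

    ``query_start`` is 1-based in oriented-query coordinates; the
    corresponding forward-query start is recoverable given the query length
    (``forward_start``).
    """

    query_start: int
    ref_name: str
    namespace: str
    ref_start: int
    strand: str
    length: int = K

    @property
    def diagonal(self) -> int:
        return self.ref_start - self.query_start

    def forward_start(self, query_length: int) -> int:
        if self.strand == FORWARD:
            return self.query_start
        return query_length - (self.query_start + self.length - 1) + 1


@dataclass
class AssociationInterval:
    """A maximal gap-free run of merged overlapping/adjacent BIs on one
    diagonal (oriented-query coordinates, 1-based inclusive)."""

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    ref_name: str
    namespace: str
    strand: str

    @property
    def diagonal(self) -> int:
        return self.ref_start - self.query_start

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


def scan_query(query: str, db: ReferenceDatabase) -> list[BasicIntervalHit]:
    """Every (query decamer, reference position) match over all references
    and both strands.  Decamers containing ambiguous bases are skipped."""
    if len(query) < K:
        raise ValueError(f"query shorter than {K} nt is unmappable")
    hits: list[BasicIntervalHit] = []
    for strand, oriented in ((FORWARD, query), (REVERSE, reverse_complement(query))):
        keys, starts = query_window_keys(oriented)
        for key, qs in zip(keys.tolist(), starts.tolist()):
            for idx in db.indexes():
                for rs in idx.lookup(key).tolist():
                    hits.append(
                        BasicIntervalHit(qs, idx.ref_name, idx.namespace, int(rs), strand)
                    )
    return hits


def merge_hits(hits: Iterable[BasicIntervalHit]) -> list[AssociationInterval]:
    """Coalesce hits sharing (reference, strand, diagonal) whose query
    ranges overlap or abut into maximal association intervals.

    Merging is idempotent and independent of input order; the result is
    sorted by (namespace, ref_name, strand, query_start, ref_start).
    """
    groups: dict[tuple[str, str, str, int], list[BasicIntervalHit]] = {}
    for h in hits:
        groups.setdefault((h.namespace, h.ref_name, h.strand, h.diagonal), []).append(h)

    out: list[AssociationInterval] = []
    for (ns, name, strand, diag), members in groups.items():
        starts = sorted({m.query_start for m in members})
        cur_s = cur_e = None
        for qs in starts:
            qe = qs + K - 1
            if cur_s is None:
                cur_s, cur_e = qs, qe
            elif qs <= cur_e + 1:  # overlap or abutment on the same diagonal
                cur_e = max(cur_e, qe)
            else:
                out.append(
                    AssociationInterval(cur_s, cur_e, cur_s + diag, cur_e + diag, name, ns, strand)
                )
                cur_s, cur_e = qs, qe
        if cur_s is not None:
            out.append(
                AssociationInterval(cur_s, cur_e, cur_s + diag, cur_e + diag, name, ns, strand)
            )
    out.sort(key=lambda ai: (ai.namespace, ai.ref_name, ai.strand, ai.query_start, ai.ref_start))
    return out
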