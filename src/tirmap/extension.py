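"""SW1 extension of association intervals and merging of extended intervals.

An association interval (an exact gap-free match) is extended outwards one
position at a time on each margin.  At every step the score of a gliding
window — the up-to-four most recently entered positions — is computed from
match/mismatch contributions only (extension is gap-free; indels are left to
the banded full alignment, SW2/SW3).  A margin stops when its window score
drops below ``window_threshold``; trailing mismatch columns are then
retracted so that the extended interval (EI) always ends on a match and
never shrinks below its seed.  This tolerates isolated SNPs (window MMMX
scores +5 at defaults) while halting quickly in unrelated sequence.

Overlapping or abutting EIs on the same reference/strand whose diagonals
differ by at most ``max_diagonal_drift`` are merged into MEIs, which are the
units handed to the full Smith-Waterman stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import AlignmentParams, DEFAULT_PARAMS
from .seeding import AssociationInterval

WINDOW = 4  # gliding-window width (nt)


@dataclass
class ExtendedInterval:
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    ref_name: str
    namespace: str
    strand: str
    window_scores: list[float] = field(default_factory=list)  # diagnostic trail

    @property
    def diagonal(self) -> int:
        return self.ref_start - self.query_start


@dataclass
class MergedExtendedInterval:
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    ref_name: str
    namespace: str
    strand: str
    members: list[ExtendedInterval] = field(default_factory=list)


def _extend_margin(
    query: str,
    ref: str,
    qpos: int,
    rpos: int,
    step: int,
    params: AlignmentParams,
    trail: list[float],
) -> int:
    """Walk one margin outward from (qpos, rpos) with stride ``step``
    (+1 right, -1 left).  Returns the signed number of columns kept after
    retracting trailing mismatches."""
    recent: list[float] = []
    kept = 0
    taken = 0
    q, r = qpos + step, rpos + step
    while 1 <= q <= len(query) and 1 <= r <= len(ref):
        is_match = query[q - 1] == ref[r - 1] and query[q - 1] in "ACGT"
        contrib = params.match if is_match else -params.mismatch_penalty
        recent.append(contrib)
        if len(recent) > WINDOW:
            recent.pop(0)
        score = sum(recent)
        trail.append(score)
        if score < params.window_threshold:
            break
        taken += 1
        if is_match:
            kept = taken
        q += step
        r += step
    return kept


def extend_interval(
    ai: AssociationInterval,
    query: str,
    ref: str,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ExtendedInterval:
    """Extend both margins of an (exact-match) association interval.

    ``query`` must be the oriented query the interval was seeded on; ``ref``
    the forward reference sequence.  The EI never shrinks below the seed.
    """
    trail: list[float] = []
    left = _extend_margin(query, ref, ai.query_start, ai.ref_start, -1, params, trail)
    right = _extend_margin(query, ref, ai.query_end, ai.ref_end, +1, params, trail)
    return ExtendedInterval(
        ai.query_start - left,
        ai.query_end + right,
        ai.ref_start - left,
        ai.ref_end + right,
        ai.ref_name,
        ai.namespace,
        ai.strand,
        trail,
    )


def merge_extended(
    eis: list[ExtendedInterval],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[MergedExtendedInterval]:
    """Merge EIs on the same (reference, strand) whose query ranges overlap
    or abut and whose diagonals differ by <= ``max_diagonal_drift``; all
    others pass through as singleton MEIs."""
    groups: dict[tuple[str, str, str], list[ExtendedInterval]] = {}
    for ei in eis:
        groups.setdefault((ei.namespace, ei.ref_name, ei.strand), []).append(ei)

    out: list[MergedExtendedInterval] = []
    for (ns, name, strand), members in groups.items():
        members = sorted(members, key=lambda e: (e.query_start, e.ref_start))
        clusters: list[list[ExtendedInterval]] = []
        for ei in members:
            placed = False
            for cl in clusters:
                q_end = max(e.query_end for e in cl)
                q_start = min(e.query_start for e in cl)
                overlaps = ei.query_start <= q_end + 1 and ei.query_end >= q_start - 1
                drift_ok = any(
                    abs(ei.diagonal - e.diagonal) <= params.max_diagonal_drift for e in cl
                )
                if overlaps and drift_ok:
                    cl.append(ei)
                    placed = True
                    break
            if not placed:
                clusters.append([ei])
        for cl in clusters:
            out.append(
                MergedExtendedInterval(
                    min(e.query_start for e in cl),
                    max(e.query_end for e in cl),
                    min(e.ref_start for e in cl),
                    max(e.ref_end for e in cl),
                    name,
                    ns,
                    strand,
                    cl,
                )
            )
    out.sort(key=lambda m: (m.namespace, m.ref_name, m.strand, m.query_start, m.ref_start))
    return out
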