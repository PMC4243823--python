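"""Pairwise germline-segment alignment with Karlin-Altschul E-values.

Alignments are computed with edlib in infix ("HW") mode — the germline
segment is the query, the read the target, and target ends are free. The
unit-cost edit alignment is then re-scored like an ungapped local hit:
terminal indel runs are treated as soft clipping (reads routinely cover
only part of a segment and vice versa), matches score +1, mismatches and
internal indel columns -2. E = K * m * n * exp(-lambda * S) with the
standard ungapped parameters for +1/-2 nucleotide scoring.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib

from .synthetic import GermlineSegment, reverse_complement

KA_LAMBDA = 1.28
KA_K = 0.46
MATCH = 1
MISMATCH = -2
GAP = -2

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class SegmentHit:
    """Best placement of a germline segment on a read."""

    gene_name: str
    score: int
    evalue: float
    target_start: int  # 0-based half-open span on the read
    target_end: int
    query_start: int  # span of the segment actually aligned (after soft clip)
    query_end: int
    strand: str  # "+" or "-" relative to the read as given
    cigar: tuple[tuple[int, str], ...]  # clipped cigar, query vs target
    query_op: str = "I"  # which of I/D consumes the query in this cigar


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def evalue_from_score(score: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def align_segment(segment: GermlineSegment, read_seq: str) -> SegmentHit | None:
    """Align a segment to the forward strand of a read; None if edlib finds
    no alignment (empty read)."""
    if not read_seq:
        return None
    res = edlib.align(segment.sequence, read_seq, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    t_start, t_end_incl = res["locations"][0]
    ops = _parse_cigar(res["cigar"])

    # edlib cigar ops are query-vs-target; determine which of I/D consumes
    # the query by checking which interpretation reproduces the query length.
    q_len_id = sum(n for n, op in ops if op in "=XI")
    consumes_query = "I" if q_len_id == len(segment.sequence) else "D"

    # soft-clip terminal indel runs (edlib charges them; a local aligner would not)
    lead_q = lead_t = 0
    while ops and ops[0][1] in "ID":
        n, op = ops.pop(0)
        if op == consumes_query:
            lead_q += n
        else:
            lead_t += n
    trail_q = trail_t = 0
    while ops and ops[-1][1] in "ID":
        n, op = ops.pop()
        if op == consumes_query:
            trail_q += n
        else:
            trail_t += n
    if not ops:
        return None

    matches = sum(n for n, op in ops if op == "=")
    mismatches = sum(n for n, op in ops if op == "X")
    indels = sum(n for n, op in ops if op in "ID")
    score = MATCH * matches + MISMATCH * mismatches + GAP * indels
    ev = evalue_from_score(score, len(segment.sequence), len(read_seq))
    return SegmentHit(
        gene_name=segment.gene_name,
        score=score,
        evalue=ev,
        target_start=t_start + lead_t,
        target_end=t_end_incl + 1 - trail_t,
        query_start=lead_q,
        query_end=len(segment.sequence) - trail_q,
        strand="+",
        cigar=tuple(ops),
        query_op=consumes_query,
    )


def best_hit(
    segments: list[GermlineSegment], read_seq: str, both_strands: bool = True
) -> SegmentHit | None:
    """Best-scoring hit over segments (and strands); ties broken by
    lexicographic gene name so results are deterministic."""
    candidates: list[SegmentHit] = []
    for seg in segments:
        hit = align_segment(seg, read_seq)
        if hit is not None:
            candidates.append(hit)
        if both_strands:
            rc_hit = align_segment(seg, reverse_complement(read_seq))
            if rc_hit is not None:
                candidates.append(
                    SegmentHit(
                        gene_name=rc_hit.gene_name,
                        score=rc_hit.score,
                        evalue=rc_hit.evalue,
                        target_start=rc_hit.target_start,
                        target_end=rc_hit.target_end,
                        query_start=rc_hit.query_start,
                        query_end=rc_hit.query_end,
                        strand="-",
                        cigar=rc_hit.cigar,
                        query_op=rc_hit.query_op,
                    )
                )
    if not candidates:
        return None
    return min(candidates, key=lambda h: (-h.score, h.gene_name, h.strand))


def map_query_to_target(hit: SegmentHit, query_pos: int) -> int:
    """Map a 0-based segment coordinate through the alignment onto the read
    (coordinates on the strand the hit was computed against). Positions in
    soft-clipped segment ends are extrapolated linearly."""
    if query_pos < hit.query_start:
        return max(0, hit.target_start - (hit.query_start - query_pos))
    q = hit.query_start
    t = hit.target_start
    consumes_query = hit.query_op
    for n, op in hit.cigar:
        if op in "=X":
            if q + n > query_pos:
                return t + (query_pos - q)
            q += n
            t += n
        elif op == consumes_query:
            if q + n > query_pos:
                return t
            q += n
        else:
            t += n
    return hit.target_end + (query_pos - hit.query_end)
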