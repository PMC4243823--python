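"""Amplicon read preparation: quality filtering, Ig-similarity retention and
orientation, primer trimming, platform length filters, capture-window
trimming, and V/J germline gene assignment.

Every stage returns a subset of its input reads (monotone pipeline); stage
in/out counts accumulate in a :class:`FilterReport`. Coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace

from . import align
from .synthetic import GermlineReference, Read, ReadSet, reverse_complement

logger = logging.getLogger(__name__)

#: Platform length-filter presets: reads are retained iff strictly longer.
PLATFORM_MIN_LENGTH = {"454": 255, "miseq": 120, "capture": 160}


@dataclass
class FilterConfig:
    """Thresholds for the read-preparation pipeline.

    min_median_phred: a read is kept iff its median per-base Phred score is
    strictly greater than this (even-length median = mean of central pair).
    ig_evalue: retention threshold for similarity to any germline V segment.
    gene_call_evalue: threshold for the V/J gene assignment step.
    min_length: strict lower bound on read length (platform dependent).
    """

    min_median_phred: int = 32
    ig_evalue: float = 1e-10
    gene_call_evalue: float = 1e-20
    min_length: int = 120
    require_both_primers: bool = True
    primer_search_window: int = 40
    primer_max_mismatches: int = 1

    def __post_init__(self) -> None:
        if self.ig_evalue <= 0 or self.gene_call_evalue <= 0:
            raise ValueError("E-value thresholds must be positive")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")

    @classmethod
    def for_platform(cls, platform: str, **overrides) -> "FilterConfig":
        if platform not in PLATFORM_MIN_LENGTH:
            raise ValueError(
                f"unknown platform {platform!r}; expected one of {sorted(PLATFORM_MIN_LENGTH)}"
            )
        return cls(min_length=PLATFORM_MIN_LENGTH[platform], **overrides)


@dataclass
class AnnotatedSequence:
    """A processed read with germline gene calls.

    Spans are 0-based half-open intervals on ``sequence`` (oriented to begin
    with the V gene); ``junction_span`` is the CDR3 window between the V and
    J anchors. ``read_count`` is the multiplicity after exact-sequence
    deduplication.
    """

    read_id: str
    sequence: str
    v_gene: str
    j_gene: str
    v_span: tuple[int, int]
    j_span: tuple[int, int]
    junction_span: tuple[int, int]
    read_count: int = 1

    def __post_init__(self) -> None:
        if not (self.v_span[1] <= self.j_span[0] <= len(self.sequence)):
            raise ValueError(
                f"{self.read_id}: inconsistent spans v={self.v_span} j={self.j_span} "
                f"len={len(self.sequence)}"
            )
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class FilterReport:
    """Per-stage in/out read counts; counts are non-increasing downstream."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        if self.stages and n_in > self.stages[-1][2]:
            raise ValueError("stage input exceeds previous stage output")
        self.stages.append((stage, n_in, n_out))
        logger.info("stage %s: %d -> %d reads", stage, n_in, n_out)

    @property
    def fraction_usable(self) -> float:
        if not self.stages or self.stages[0][1] == 0:
            return 0.0
        return self.stages[-1][2] / self.stages[0][1]


# ---------------------------------------------------------------------------
# filtering stages
# ---------------------------------------------------------------------------

def _median_phred(quality: str) -> float:
    return statistics.median(ord(c) - 33 for c in quality)


def quality_filter(reads: ReadSet, min_median_phred: int = 32) -> ReadSet:
    """Keep reads whose median per-base Phred score strictly exceeds the
    threshold. Malformed quality strings drop the read with a warning."""
    kept = []
    for read in reads.reads:
        try:
            if any(ord(c) < 33 or ord(c) > 126 for c in read.quality):
                raise ValueError("quality characters outside Phred+33 range")
            med = _median_phred(read.quality)
        except ValueError as exc:
            logger.warning("read %s: malformed quality (%s); dropped", read.read_id, exc)
            continue
        if med > min_median_phred:
            kept.append(read)
    return ReadSet(kept, dict(reads.metadata))


def retain_ig_similar(
    reads: ReadSet, reference: GermlineReference, evalue: float = 1e-10
) -> ReadSet:
    """Keep reads with a local-alignment hit to any germline V segment at
    E-value <= threshold, searched on both strands; minus-strand hits are
    reverse-complemented so every retained read begins with the V gene."""
    if not reference.v_segments:
        raise ValueError("empty reference")
    # align each unique sequence once; duplicates inherit the decision
    decisions: dict[str, str | None] = {}
    kept = []
    for read in reads.reads:
        if read.sequence not in decisions:
            hit = align.best_hit(list(reference.v_segments), read.sequence, both_strands=True)
            if hit is None or hit.evalue > evalue:
                decisions[read.sequence] = None
            else:
                decisions[read.sequence] = hit.strand
        strand = decisions[read.sequence]
        if strand is None:
            continue
        if strand == "-":
            read = Read(read.read_id, reverse_complement(read.sequence), read.quality[::-1])
        kept.append(read)
    return ReadSet(kept, dict(reads.metadata))


def _find_primer(seq: str, primer: str, max_mismatches: int) -> tuple[int, int] | None:
    """Best sliding-window Hamming match of primer in seq; None if the best
    exceeds max_mismatches. Ties go to the leftmost placement."""
    if len(primer) > len(seq):
        return None
    best = None
    for start in range(len(seq) - len(primer) + 1):
        mm = sum(a != b for a, b in zip(primer, seq[start: start + len(primer)]))
        if mm <= max_mismatches and (best is None or mm < best[2]):
            best = (start, start + len(primer), mm)
            if mm == 0:
                break
    return None if best is None else best[:2]


def trim_primers(
    reads: ReadSet,
    forward_primers: list[str],
    reverse_primer: str,
    max_mismatches: int = 1,
    search_window: int = 40,
) -> ReadSet:
    """Trim primers; keep a read only when one forward primer matches within
    the first ``search_window`` bases and the reverse primer (searched as its
    reverse complement, reads being V-oriented) matches within the last
    ``search_window`` bases, each with <= max_mismatches substitutions."""
    if not forward_primers:
        raise ValueError("empty forward primer list")
    rev = reverse_complement(reverse_primer)
    kept = []
    for read in reads.reads:
        head = read.sequence[:search_window]
        fwd_match = None
        for primer in forward_primers:
            fwd_match = _find_primer(head, primer, max_mismatches)
            if fwd_match is not None:
                break
        if fwd_match is None:
            continue
        tail_off = max(0, len(read.sequence) - search_window)
        rev_match = _find_primer(read.sequence[tail_off:], rev, max_mismatches)
        if rev_match is None:
            rev_match = _find_primer(read.sequence[tail_off:], reverse_primer, max_mismatches)
        if rev_match is None:
            continue
        start = fwd_match[1]
        end = tail_off + rev_match[0]
        if end <= start:
            continue
        kept.append(Read(read.read_id, read.sequence[start:end], read.quality[start:end]))
    return ReadSet(kept, dict(reads.metadata))


def length_filter(reads: ReadSet, min_length: int) -> ReadSet:
    """Keep reads strictly longer than min_length."""
    return ReadSet(
        [r for r in reads.reads if len(r.sequence) > min_length], dict(reads.metadata)
    )


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

def assign_genes(
    reads: ReadSet,
    reference: GermlineReference,
    gene_call_evalue: float = 1e-20,
    dedupe: bool = True,
) -> list[AnnotatedSequence]:
    """Assign V and J germline genes to each read by best local-alignment
    score at E-value <= threshold; reads lacking a qualifying V or J hit are
    dropped (and counted in the log). Ties between equal-scoring genes break
    lexicographically (deterministic, logged at debug level).

    Identical sequences are collapsed before alignment; ``read_count``
    carries the multiplicity.
    """
    groups: dict[str, list[Read]] = {}
    order: list[str] = []
    for read in reads.reads:
        if read.sequence not in groups:
            groups[read.sequence] = []
            order.append(read.sequence)
        groups[read.sequence].append(read)
    if not dedupe:
        order = [r.sequence for r in reads.reads]

    annotated: list[AnnotatedSequence] = []
    n_dropped = 0
    for seq in order:
        members = groups[seq]
        v_hit = align.best_hit(list(reference.v_segments), seq, both_strands=False)
        j_hit = align.best_hit(list(reference.j_segments), seq, both_strands=False)
        if v_hit is None or v_hit.evalue > gene_call_evalue:
            n_dropped += len(members)
            continue
        if j_hit is None or j_hit.evalue > gene_call_evalue:
            n_dropped += len(members)
            continue
        v_seg = reference.segment(v_hit.gene_name)
        j_seg = reference.segment(j_hit.gene_name)
        v_anchor_on_read = align.map_query_to_target(v_hit, v_seg.anchor)
        j_anchor_on_read = align.map_query_to_target(j_hit, j_seg.anchor)
        v_span = (v_hit.target_start, v_hit.target_end)
        j_span = (max(j_hit.target_start, v_hit.target_end), max(j_hit.target_end, v_hit.target_end))
        junction = (
            min(max(v_anchor_on_read, 0), len(seq)),
            min(max(j_anchor_on_read, v_anchor_on_read), len(seq)),
        )
        annotated.append(
            AnnotatedSequence(
                read_id=members[0].read_id,
                sequence=seq,
                v_gene=v_hit.gene_name,
                j_gene=j_hit.gene_name,
                v_span=v_span,
                j_span=j_span,
                junction_span=junction,
                read_count=len(members) if dedupe else 1,
            )
        )
    if n_dropped:
        logger.info("assign_genes: dropped %d reads with no qualifying V/J hit", n_dropped)
    return annotated


def trim_capture_reads(annotated: list[AnnotatedSequence]) -> list[AnnotatedSequence]:
    """Crop each read to the IgHV..IgHJ region [v_span.start, j_span.end)
    and re-base all spans; idempotent."""
    out = []
    for ann in annotated:
        start, end = ann.v_span[0], ann.j_span[1]
        if start == 0 and end == len(ann.sequence):
            out.append(ann)
            continue
        shift = start
        out.append(
            replace(
                ann,
                sequence=ann.sequence[start:end],
                v_span=(0, ann.v_span[1] - shift),
                j_span=(ann.j_span[0] - shift, end - shift),
                junction_span=(
                    max(0, ann.junction_span[0] - shift),
                    max(0, ann.junction_span[1] - shift),
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# orchestrated pipeline
# ---------------------------------------------------------------------------

def process_reads(
    reads: ReadSet,
    reference: GermlineReference,
    config: FilterConfig | None = None,
    forward_primers: list[str] | None = None,
    reverse_primer: str | None = None,
    capture_trim: bool = False,
) -> tuple[list[AnnotatedSequence], FilterReport]:
    """Run the full preparation pipeline and return annotated sequences plus
    the per-stage filter report. Primer trimming runs only when primers are
    supplied; capture-window trimming only when ``capture_trim`` is set."""
    config = config or FilterConfig()
    report = FilterReport()

    n_in = len(reads)
    reads = quality_filter(reads, config.min_median_phred)
    report.add("quality", n_in, len(reads))

    n_in = len(reads)
    reads = retain_ig_similar(reads, reference, config.ig_evalue)
    report.add("ig_similarity", n_in, len(reads))

    if forward_primers and reverse_primer:
        n_in = len(reads)
        reads = trim_primers(
            reads,
            forward_primers,
            reverse_primer,
            config.primer_max_mismatches,
            config.primer_search_window,
        )
        report.add("primer", n_in, len(reads))

    n_in = len(reads)
    reads = length_filter(reads, config.min_length)
    report.add("length", n_in, len(reads))

    n_in = len(reads)
    annotated = assign_genes(reads, reference, config.gene_call_evalue)
    report.add("gene_call", n_in, sum(a.read_count for a in annotated))

    if capture_trim:
        annotated = trim_capture_reads(annotated)
    return annotated, report
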