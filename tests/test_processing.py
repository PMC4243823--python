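"""Read preparation: quality/similarity/primer/length filters, orientation,
gene assignment, and pipeline monotonicity."""

import math

import numpy as np
import pytest

from conftest import rng_seq
from repseq.align import KA_LAMBDA, KA_K
from repseq.processing import (
    FilterConfig,
    assign_genes,
    length_filter,
    process_reads,
    quality_filter,
    retain_ig_similar,
    trim_capture_reads,
    trim_primers,
)
from repseq.synthetic import ErrorModel, Read, ReadSet, reverse_complement, sample_reads, simulate_repertoire


def _read(seq: str, phreds=None, rid: str = "r1") -> Read:
    if phreds is None:
        quality = "I" * len(seq)  # Phred 40
    elif isinstance(phreds, int):
        quality = chr(phreds + 33) * len(seq)
    else:
        quality = "".join(chr(p + 33) for p in phreds)
    return Read(rid, seq, quality)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "phreds,kept",
        [
            (40, True),        # all above threshold
            (32, False),       # boundary: strict >
            ([20, 20, 40, 40], False),  # even-length median = 30
            ([20, 40, 40, 40], True),   # median 40
        ],
    )
    def test_median_rule(self, phreds, kept):
        reads = ReadSet([_read("ACGT" * 25 if isinstance(phreds, int) else "ACGT", phreds)])
        out = quality_filter(reads, 32)
        assert (len(out) == 1) == kept

    def test_malformed_quality_dropped_not_crash(self, caplog):
        bad = Read("bad", "ACGT", "II\x01I")
        good = _read("ACGT", 40, rid="good")
        out = quality_filter(ReadSet([bad, good]), 32)
        assert [r.read_id for r in out.reads] == ["good"]


class TestRetainIgSimilar:
    def test_exact_v_substring_retained_forward(self, ref5):
        seq = ref5.v_segments[0].sequence
        out = retain_ig_similar(ReadSet([_read(seq)]), ref5)
        assert len(out) == 1
        assert out.reads[0].sequence == seq

    def test_reverse_complement_reoriented_identically(self, ref5):
        seq = ref5.v_segments[0].sequence
        fwd = retain_ig_similar(ReadSet([_read(seq)]), ref5)
        rev = retain_ig_similar(ReadSet([_read(reverse_complement(seq))]), ref5)
        assert fwd.reads[0].sequence == rev.reads[0].sequence

    def test_random_read_removed(self, ref5):
        """A random 200-mer has no local alignment anywhere near the E-value
        threshold; cross-checked with a brute-force Smith-Waterman bound."""
        rng = np.random.default_rng(123)
        seq = rng_seq(rng, 200)
        out = retain_ig_similar(ReadSet([_read(seq)]), ref5, evalue=1e-10)
        assert len(out) == 0
        # brute-force SW (match +1, mismatch/gap -2) against each V segment
        def sw_score(a: str, b: str) -> int:
            prev = [0] * (len(b) + 1)
            best = 0
            for i in range(1, len(a) + 1):
                cur = [0] * (len(b) + 1)
                for j in range(1, len(b) + 1):
                    diag = prev[j - 1] + (1 if a[i - 1] == b[j - 1] else -2)
                    cur[j] = max(0, diag, prev[j] - 2, cur[j - 1] - 2)
                    best = max(best, cur[j])
                prev = cur
            return best

        for strand_seq in (seq, reverse_complement(seq)):
            for seg in ref5.v_segments:
                s = sw_score(strand_seq, seg.sequence)
                evalue = KA_K * len(seq) * len(seg.sequence) * math.exp(-KA_LAMBDA * s)
                assert evalue > 1e-10

    def test_empty_reference_rejected(self, ref5):
        import dataclasses
        with pytest.raises(Exception):
            bad = dataclasses.replace(ref5, v_segments=())
            retain_ig_similar(ReadSet([_read("ACGT" * 50)]), bad)


class TestTrimPrimers:
    FWD = "ACGTACGTACGTACGTACGT"
    REV = "TTGGCCAATTGGCCAATTGG"

    def _assemble(self, insert: str) -> str:
        return self.FWD + insert + reverse_complement(self.REV)

    def test_exact_primers_trimmed_to_insert(self):
        insert = "AAACCCGGGTTT" * 10
        reads = ReadSet([_read(self._assemble(insert))])
        out = trim_primers(reads, [self.FWD], self.REV, max_mismatches=0)
        assert out.reads[0].sequence == insert

    def test_missing_reverse_primer_removed(self):
        insert = "AAACCCGGGTTT" * 10
        reads = ReadSet([_read(self.FWD + insert)])
        out = trim_primers(reads, [self.FWD], self.REV, max_mismatches=0)
        assert len(out) == 0

    def test_one_mismatch_tolerated(self):
        insert = "AAACCCGGGTTT" * 10
        fwd_1mm = "T" + self.FWD[1:]
        reads = ReadSet([_read(fwd_1mm + insert + reverse_complement(self.REV))])
        assert len(trim_primers(reads, [self.FWD], self.REV, max_mismatches=0)) == 0
        out = trim_primers(reads, [self.FWD], self.REV, max_mismatches=1)
        assert out.reads[0].sequence == insert

    def test_empty_primer_list_rejected(self):
        with pytest.raises(ValueError):
            trim_primers(ReadSet([_read("ACGT" * 30)]), [], self.REV)


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(256, True), (255, False), (254, False)])
    def test_strict_boundary(self, length, kept):
        out = length_filter(ReadSet([_read("A" * length)]), 255)
        assert (len(out) == 1) == kept

    def test_empty_readset(self):
        assert len(length_filter(ReadSet([]), 255)) == 0


class TestAssignGenes:
    def test_error_free_calls_match_ground_truth(self, ref5, small_readset):
        rep, reads = small_readset
        seq2genes = {}
        for clone in rep.clones:
            for seq, _ in clone.shm_lineage:
                seq2genes[seq] = (clone.v_gene, clone.j_gene)
        annotated = assign_genes(reads, ref5)
        assert sum(a.read_count for a in annotated) == len(reads)
        for ann in annotated:
            assert (ann.v_gene, ann.j_gene) == seq2genes[ann.sequence]

    def test_three_substitutions_keep_gene_call(self, ref5):
        rng = np.random.default_rng(77)
        v = ref5.v_segments[2]
        j = ref5.j_segments[0]
        seq = list(v.sequence + "ACGTACGTAC" + j.sequence)
        for pos in rng.choice(len(v.sequence), size=3, replace=False):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        annotated = assign_genes(ReadSet([_read("".join(seq))]), ref5)
        assert annotated[0].v_gene == v.gene_name
        assert annotated[0].j_gene == j.gene_name

    def test_junction_span_matches_anchors(self, ref5):
        v = ref5.v_segments[0]
        j = ref5.j_segments[1]
        insert = "ACGTACGTACGT"
        annotated = assign_genes(ReadSet([_read(v.sequence + insert + j.sequence)]), ref5)
        ann = annotated[0]
        assert ann.junction_span == (
            v.anchor,
            len(v.sequence) + len(insert) + j.anchor,
        )
        assert ann.v_span[1] <= ann.j_span[0] <= len(ann.sequence)

    def test_junk_reads_dropped(self, ref5):
        rng = np.random.default_rng(5)
        annotated = assign_genes(ReadSet([_read(rng_seq(rng, 260))]), ref5)
        assert annotated == []


class TestTrimCaptureReads:
    def test_adaptor_removed_and_idempotent(self, ref5):
        v = ref5.v_segments[0]
        j = ref5.j_segments[0]
        adaptor = "GGGGGTTTTTCCCCCAAAAA"
        read = _read(adaptor + v.sequence + "ACGTACGTAC" + j.sequence + adaptor)
        annotated = assign_genes(ReadSet([read]), ref5)
        trimmed = trim_capture_reads(annotated)
        assert trimmed[0].sequence == v.sequence + "ACGTACGTAC" + j.sequence
        assert trimmed[0].v_span[0] == 0
        assert trimmed[0].j_span[1] == len(trimmed[0].sequence)
        assert trim_capture_reads(trimmed) == trimmed

    def test_exact_span_unchanged(self, ref5):
        v = ref5.v_segments[0]
        j = ref5.j_segments[0]
        annotated = assign_genes(ReadSet([_read(v.sequence + "ACGTACGTAC" + j.sequence)]), ref5)
        assert trim_capture_reads(annotated) == annotated

    def test_cropped_length_equals_vj_span(self, ref5, small_readset):
        _, reads = small_readset
        subset = ReadSet(reads.reads[:100], dict(reads.metadata))
        annotated = assign_genes(subset, ref5)
        for ann in trim_capture_reads(annotated):
            assert len(ann.sequence) == ann.j_span[1] - ann.v_span[0]


class TestPipeline:
    def test_stage_counts_monotone(self, ref5):
        rep = simulate_repertoire(ref5, "healthy", 100, seed=21)
        reads = sample_reads(
            rep, 1000, error_model=ErrorModel.miseq_like(), seed=22, low_quality_fraction=0.2
        )
        # spike in junk reads that fail the similarity filter
        rng = np.random.default_rng(23)
        junk = [
            Read(f"junk_{i}", rng_seq(rng, 260), "G" * 260) for i in range(50)
        ]
        readset = ReadSet(reads.reads + junk, dict(reads.metadata))
        annotated, report = process_reads(readset, ref5, FilterConfig(min_length=120))
        counts = [n_in for _, n_in, _ in report.stages] + [report.stages[-1][2]]
        assert counts == sorted(counts, reverse=True)
        assert report.stages[0][1] == 1050
        assert 0 < report.fraction_usable < 1
        assert sum(a.read_count for a in annotated) == report.stages[-1][2]

    def test_strand_invariance(self, ref5, small_readset):
        _, reads = small_readset
        subset = ReadSet(reads.reads[:300], dict(reads.metadata))
        flipped = ReadSet(
            [
                Read(r.read_id, reverse_complement(r.sequence), r.quality[::-1])
                for r in subset.reads
            ],
            dict(subset.metadata),
        )
        ann_fwd, _ = process_reads(subset, ref5, FilterConfig(min_length=120))
        ann_rev, _ = process_reads(flipped, ref5, FilterConfig(min_length=120))
        key = lambda anns: sorted((a.sequence, a.read_count, a.v_gene, a.j_gene) for a in anns)
        assert key(ann_fwd) == key(ann_rev)

    def test_unknown_platform_rejected(self):
        with pytest.raises(ValueError, match="platform"):
            FilterConfig.for_platform("nanopore")

    @pytest.mark.parametrize("platform,min_length", [("454", 255), ("miseq", 120), ("capture", 160)])
    def test_platform_presets(self, platform, min_length):
        assert FilterConfig.for_platform(platform).min_length == min_length
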