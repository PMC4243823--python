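"""Comparison statistics: regressions, paired tests, trimming windows,
sequence overlap."""

import numpy as np
import pytest

from repseq.comparison import (
    TrimWindow,
    compare_usage,
    paired_gene_tests,
    sequence_overlap,
    trim_to_window,
    trimming_experiment,
)
from repseq.network import build_network
from repseq.processing import AnnotatedSequence
from repseq.usage import GeneUsageTable


def _table(freqs: dict, sample="s") -> GeneUsageTable:
    return GeneUsageTable(sample, freqs, n_reads=1000)


def _ann(seq, v_span, j_span, junction, count=1, rid=None):
    return AnnotatedSequence(
        read_id=rid or f"r{hash((seq, count)) & 0xFFFF}",
        sequence=seq,
        v_gene="IGHV1-toy",
        j_gene="IGHJ1-toy",
        v_span=v_span,
        j_span=j_span,
        junction_span=junction,
        read_count=count,
    )


class TestCompareUsage:
    def test_identical_tables(self):
        t = _table({"A": 0.6, "B": 0.3, "C": 0.1})
        res = compare_usage(t, t)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_linear_scaling(self):
        ta = _table({"A": 0.1, "B": 0.2, "C": 0.7})
        tb = GeneUsageTable("b", {"A": 0.2, "B": 0.4, "C": 1.4}, 0)
        res = compare_usage(ta, tb)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_symmetry_and_slope_product(self):
        rng = np.random.default_rng(3)
        fa = rng.dirichlet(np.ones(10))
        fb = rng.dirichlet(np.ones(10))
        genes = [f"G{i}" for i in range(10)]
        ta = _table(dict(zip(genes, fa)))
        tb = _table(dict(zip(genes, fb)))
        ab = compare_usage(ta, tb)
        ba = compare_usage(tb, ta)
        assert ab.r_squared == pytest.approx(ba.r_squared)
        assert ab.slope * ba.slope <= 1.0 + 1e-12

    def test_subset_threshold_restricts_points(self):
        ta = _table({"A": 0.8, "B": 0.1, "C": 0.1})
        tb = _table({"A": 0.78, "B": 0.12, "C": 0.1})
        res = compare_usage(ta, tb, subset_threshold=0.15)
        assert res.n_points == 2  # B and C only

    def test_too_few_points_rejected(self):
        ta = _table({"A": 1.0})
        with pytest.raises(ValueError):
            compare_usage(ta, ta)


class TestPairedGeneTests:
    def test_identical_methods_no_significant_genes(self):
        rng = np.random.default_rng(8)
        tables = [
            _table(dict(zip("ABCDE", rng.dirichlet(np.ones(5)))), f"s{i}") for i in range(6)
        ]
        res = paired_gene_tests(tables, tables)
        assert res.significant_genes == []
        assert all(p == 1.0 for p in res.wilcoxon_p.values())

    def test_shifted_gene_detected(self):
        rng = np.random.default_rng(9)
        t1, t2 = [], []
        for i in range(8):
            base = rng.dirichlet(np.ones(5) * 20)
            t1.append(_table(dict(zip("ABCDE", base)), f"s{i}"))
            shifted = base.copy()
            shifted[0] += 0.3 + rng.normal(0, 0.005)  # method effect on gene A
            shifted /= shifted.sum()
            t2.append(_table(dict(zip("ABCDE", shifted / shifted.sum())), f"s{i}"))
        res = paired_gene_tests(t1, t2)
        assert "A" in res.significant_genes
        assert res.ttest_p_adjusted["A"] < 0.05

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(10)
        t1 = [_table(dict(zip("ABCD", rng.dirichlet(np.ones(4)))), f"s{i}") for i in range(5)]
        t2 = [_table(dict(zip("ABCD", rng.dirichlet(np.ones(4)))), f"s{i}") for i in range(5)]
        res = paired_gene_tests(t1, t2)
        for g in res.genes:
            assert res.wilcoxon_p_adjusted[g] >= res.wilcoxon_p[g]
            assert res.ttest_p_adjusted[g] >= res.ttest_p[g]

    def test_mismatched_lists_rejected(self):
        t = _table({"A": 1.0})
        with pytest.raises(ValueError):
            paired_gene_tests([t, t], [t])


class TestTrimToWindow:
    def test_race_mode_keeps_250_from_j_end(self):
        seq = "".join("ACGT"[i % 4] for i in range(600))
        ann = _ann(seq, v_span=(0, 300), j_span=(550, 600), junction=(290, 560))
        out = trim_to_window([ann], TrimWindow("race_250_from_J_end"))
        assert out[0].sequence == seq[350:600]
        assert len(out[0].sequence) == 250

    def test_short_read_unchanged(self):
        seq = "ACGTACGTACGT" * 10  # 120 nt < 250
        ann = _ann(seq, v_span=(0, 60), j_span=(100, 120), junction=(50, 110))
        out = trim_to_window([ann], TrimWindow("race_250_from_J_end"))
        assert out[0].sequence == seq

    def test_cdr3_mode_output_length_is_junction_length(self):
        seq = "ACGTACGTACGT" * 20
        ann = _ann(seq, v_span=(0, 100), j_span=(200, 240), junction=(90, 210))
        out = trim_to_window([ann], TrimWindow("cdr3_only"))
        assert len(out[0].sequence) == 120
        assert out[0].sequence == seq[90:210]

    def test_capture_mode_window(self):
        seq = "ACGTACGTACGT" * 30  # 360 nt
        ann = _ann(seq, v_span=(0, 250), j_span=(300, 350), junction=(240, 310))
        out = trim_to_window([ann], TrimWindow("capture_window"))
        # [v_end - 149, j_start + 41) = [101, 341)
        assert out[0].sequence == seq[101:341]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            TrimWindow("full_length")


class TestTrimmingExperiment:
    def _shm_fixture(self):
        """Two samples whose lineage variants differ only in the first 10
        bases — outside every trimming window."""
        rng = np.random.default_rng(55)
        samples = {}
        for s in range(2):
            anns = []
            for c in range(25):
                stem = "".join("ACGT"[i] for i in rng.integers(0, 4, size=260))
                # full-length annotated read: V=[0,200), junction=[190,220), J=[210,260)
                base = _ann(stem, (0, 200), (210, 260), (190, 220), count=5, rid=f"s{s}c{c}")
                mut0 = "T" if stem[0] != "T" else "A"
                mut4 = "G" if stem[4] != "G" else "C"
                variant_seq = mut0 + stem[1:4] + mut4 + stem[5:]
                variant = _ann(variant_seq, (0, 200), (210, 260), (190, 220), count=2,
                               rid=f"s{s}c{c}v")
                anns.extend([base, variant])
            samples[f"sample{s}"] = anns
        return samples

    def test_unique_count_never_increases(self):
        samples = self._shm_fixture()
        windows = [
            TrimWindow("race_250_from_J_end"),
            TrimWindow("cdr3_only"),
            TrimWindow("capture_window"),
        ]
        exp = trimming_experiment(samples, windows)
        full = exp.table[exp.table.window == "full"].set_index("sample")["n_unique"]
        for window in windows:
            sub = exp.table[exp.table.window == window.mode].set_index("sample")["n_unique"]
            assert (sub <= full).all()

    def test_mutations_outside_windows_merge_vertices(self):
        samples = self._shm_fixture()
        windows = [
            TrimWindow("race_250_from_J_end"),
            TrimWindow("cdr3_only"),
            TrimWindow("capture_window"),
        ]
        exp = trimming_experiment(samples, windows)
        full = exp.table[exp.table.window == "full"].set_index("sample")["n_unique"]
        for window in windows:
            sub = exp.table[exp.table.window == window.mode].set_index("sample")["n_unique"]
            assert (sub < full).all(), window.mode

    def test_full_window_is_identity(self):
        samples = self._shm_fixture()
        exp = trimming_experiment(samples, [])
        anns = samples["sample0"]
        net = build_network(anns)
        row = exp.table[(exp.table.window == "full") & (exp.table["sample"] == "sample0")]
        assert int(row["n_unique"].iloc[0]) == len(net.vertices)


class TestSequenceOverlap:
    def test_identical_repertoires(self):
        anns = [_ann("AAAA", (0, 2), (2, 4), (1, 3), count=5)]
        pct, pairs, _ = sequence_overlap(anns, anns)
        assert pct == pytest.approx(100.0)

    def test_disjoint_repertoires(self):
        a = [_ann("AAAA", (0, 2), (2, 4), (1, 3))]
        b = [_ann("CCCC", (0, 2), (2, 4), (1, 3))]
        pct, pairs, reg = sequence_overlap(a, b)
        assert pct == 0.0
        assert pairs.empty
        assert reg is None

    def test_partial_overlap_definition(self):
        a = [
            _ann("AAAA", (0, 2), (2, 4), (1, 3), count=7),
            _ann("CCCC", (0, 2), (2, 4), (1, 3), count=3),
        ]
        b = [_ann("AAAA", (0, 2), (2, 4), (1, 3), count=1)]
        pct, _, _ = sequence_overlap(a, b)
        assert pct == pytest.approx(70.0)

    def test_shared_frequency_regression(self):
        a = [
            _ann("AAAA", (0, 2), (2, 4), (1, 3), count=70),
            _ann("CCCC", (0, 2), (2, 4), (1, 3), count=30),
        ]
        b = [
            _ann("AAAA", (0, 2), (2, 4), (1, 3), count=140),
            _ann("CCCC", (0, 2), (2, 4), (1, 3), count=60),
        ]
        pct, pairs, reg = sequence_overlap(a, b)
        assert pct == pytest.approx(100.0)
        assert reg.slope == pytest.approx(1.0)  # same relative frequencies
        assert reg.r_squared == pytest.approx(1.0)
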