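"""Method-comparison machinery: frequency regressions between repeats and
methods, paired per-gene tests with Bonferroni correction, amplicon-length
trimming experiments, and RNA-vs-DNA sequence overlap."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .network import DiversitySummary, build_network, diversity_summary
from .processing import AnnotatedSequence
from .usage import GeneUsageTable, subset_low_frequency

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    """Regression-through-origin slope and squared Pearson correlation of
    paired frequencies (R^2 of the paired points, not the no-intercept R^2,
    which is non-standard)."""

    slope: float
    r_squared: float
    n_points: int
    subset_threshold: float | None = None


def _regression(x: np.ndarray, y: np.ndarray, subset_threshold=None) -> ComparisonResult:
    if x.size < 2:
        raise ValueError("regression requires at least 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x values are zero; slope undefined")
    slope = float(np.sum(x * y) / sxx)
    if np.std(x) == 0 or np.std(y) == 0:
        r2 = 1.0 if np.allclose(y, slope * x) else 0.0
    else:
        r2 = float(stats.pearsonr(x, y).statistic ** 2)
    return ComparisonResult(slope, r2, int(x.size), subset_threshold)


def compare_usage(
    tables_a: GeneUsageTable | list[GeneUsageTable],
    tables_b: GeneUsageTable | list[GeneUsageTable],
    subset_threshold: float | None = None,
) -> ComparisonResult:
    """Regress gene frequencies of B on A through the origin, pooling points
    across sample pairs when lists are given. With ``subset_threshold``,
    only genes below the threshold in both members of each pair enter."""
    if isinstance(tables_a, GeneUsageTable):
        tables_a = [tables_a]
    if isinstance(tables_b, GeneUsageTable):
        tables_b = [tables_b]
    if len(tables_a) != len(tables_b):
        raise ValueError("matched table lists must have equal length")
    xs: list[float] = []
    ys: list[float] = []
    for ta, tb in zip(tables_a, tables_b):
        if subset_threshold is not None:
            genes = subset_low_frequency(ta, tb, subset_threshold)
        else:
            genes = sorted(set(ta.frequencies) | set(tb.frequencies))
        xs.extend(ta.frequencies.get(g, 0.0) for g in genes)
        ys.extend(tb.frequencies.get(g, 0.0) for g in genes)
    return _regression(np.array(xs), np.array(ys), subset_threshold)


@dataclass
class PairedTestResult:
    genes: list[str]
    wilcoxon_p: dict[str, float]
    ttest_p: dict[str, float]
    wilcoxon_p_adjusted: dict[str, float]
    ttest_p_adjusted: dict[str, float]
    significant_genes: list[str] = field(default_factory=list)
    alpha: float = 0.05


def paired_gene_tests(
    tables_method1: list[GeneUsageTable],
    tables_method2: list[GeneUsageTable],
    alpha: float = 0.05,
) -> PairedTestResult:
    """Per gene, test frequencies of method 1 vs method 2 paired across
    samples (Wilcoxon signed-rank and paired t-test), Bonferroni-corrected
    over the genes tested. Genes whose paired differences are all exactly
    zero get p = 1; constant non-zero differences drive the t statistic to
    infinity (p = 0)."""
    if len(tables_method1) != len(tables_method2):
        raise ValueError("matched sample lists must have equal length")
    if not tables_method1:
        raise ValueError("empty sample lists")
    genes = sorted({g for t in tables_method1 + tables_method2 for g in t.frequencies})
    n_genes = len(genes)
    wilcoxon_p: dict[str, float] = {}
    ttest_p: dict[str, float] = {}
    for gene in genes:
        a = np.array([t.frequencies.get(gene, 0.0) for t in tables_method1])
        b = np.array([t.frequencies.get(gene, 0.0) for t in tables_method2])
        diff = a - b
        if np.all(diff == 0):
            logger.info("gene %s: all paired differences zero; p set to 1", gene)
            wilcoxon_p[gene] = 1.0
            ttest_p[gene] = 1.0
            continue
        if np.std(diff) == 0:
            logger.info("gene %s: constant non-zero differences; t diverges", gene)
            wilcoxon_p[gene] = float(stats.wilcoxon(diff).pvalue)
            ttest_p[gene] = 0.0
            continue
        wilcoxon_p[gene] = float(stats.wilcoxon(diff).pvalue)
        ttest_p[gene] = float(stats.ttest_rel(a, b).pvalue)
    w_adj = {g: min(1.0, p * n_genes) for g, p in wilcoxon_p.items()}
    t_adj = {g: min(1.0, p * n_genes) for g, p in ttest_p.items()}
    significant = sorted(g for g in genes if w_adj[g] < alpha or t_adj[g] < alpha)
    return PairedTestResult(genes, wilcoxon_p, ttest_p, w_adj, t_adj, significant, alpha)


# ---------------------------------------------------------------------------
# amplicon-length trimming
# ---------------------------------------------------------------------------

TRIM_MODES = ("race_250_from_J_end", "cdr3_only", "capture_window")


@dataclass(frozen=True)
class TrimWindow:
    """Amplicon trimming window.

    race_250_from_J_end: keep the bases within ``race_length`` of the IgHJ
    3' end (emulating 250 bp 5'RACE reads). cdr3_only: keep the CDR3
    junction window. capture_window: keep ``bases_from_v3prime`` upstream of
    the V 3' end through ``bases_from_j5prime`` into the J (the mean region
    covered by RNA-capture reads)."""

    mode: str
    race_length: int = 250
    bases_from_v3prime: int = 149
    bases_from_j5prime: int = 41

    def __post_init__(self) -> None:
        if self.mode not in TRIM_MODES:
            raise ValueError(f"unknown trim mode {self.mode!r}; expected one of {TRIM_MODES}")
        if min(self.race_length, self.bases_from_v3prime, self.bases_from_j5prime) <= 0:
            raise ValueError("window parameters must be positive")


def _crop(ann: AnnotatedSequence, start: int, end: int) -> AnnotatedSequence:
    start = max(0, start)
    end = min(len(ann.sequence), max(end, start))
    def clip(span):
        return (
            min(max(span[0] - start, 0), end - start),
            min(max(span[1] - start, 0), end - start),
        )
    v = clip(ann.v_span)
    j = clip(ann.j_span)
    if v[1] > j[0]:
        v = (v[0], j[0])
    return replace(
        ann,
        sequence=ann.sequence[start:end],
        v_span=v,
        j_span=j,
        junction_span=clip(ann.junction_span),
    )


def trim_to_window(
    annotated: list[AnnotatedSequence], window: TrimWindow
) -> list[AnnotatedSequence]:
    """Trim every read to the window; reads already shorter than the window
    are kept at their available length. Reads whose window is empty (e.g. a
    degenerate junction in cdr3 mode) are dropped with a log line."""
    out = []
    n_empty = 0
    for ann in annotated:
        if window.mode == "race_250_from_J_end":
            end = ann.j_span[1]
            trimmed = _crop(ann, end - window.race_length, end)
        elif window.mode == "cdr3_only":
            trimmed = _crop(ann, ann.junction_span[0], ann.junction_span[1])
        else:
            trimmed = _crop(
                ann,
                ann.v_span[1] - window.bases_from_v3prime,
                ann.j_span[0] + window.bases_from_j5prime,
            )
        if trimmed.sequence:
            out.append(trimmed)
        else:
            n_empty += 1
    if n_empty:
        logger.warning("trim_to_window(%s): dropped %d reads with empty window", window.mode, n_empty)
    return out


@dataclass
class TrimmingExperiment:
    """Per-sample, per-window unique-sequence counts and diversity, plus
    paired tests of each window against the full-length repertoires."""

    table: pd.DataFrame  # columns: sample, window, n_unique, vertex_gini, cluster_gini, max_cluster_pct
    n_unique_pvalues: dict[str, tuple[float, float]]  # window -> (wilcoxon, t-test)
    cluster_gini_pvalues: dict[str, tuple[float, float]]


def _paired_p(full: np.ndarray, trimmed: np.ndarray) -> tuple[float, float]:
    diff = full - trimmed
    if np.all(diff == 0):
        return 1.0, 1.0
    w = float(stats.wilcoxon(diff).pvalue)
    t = 0.0 if np.std(diff) == 0 else float(stats.ttest_rel(full, trimmed).pvalue)
    return w, t


def trimming_experiment(
    annotated_by_sample: dict[str, list[AnnotatedSequence]],
    windows: list[TrimWindow],
) -> TrimmingExperiment:
    """Rebuild the network per sample under each trimming window and report
    unique-sequence counts and diversity; significance of the change from
    full length is assessed by paired tests across samples."""
    rows = []
    per_window: dict[str, dict[str, tuple[int, DiversitySummary]]] = {"full": {}}
    for sample, annotated in annotated_by_sample.items():
        net = build_network(annotated)
        summ = diversity_summary(net)
        per_window["full"][sample] = (len(net.vertices), summ)
        rows.append(("full", sample, len(net.vertices), summ))
    for window in windows:
        per_window[window.mode] = {}
        for sample, annotated in annotated_by_sample.items():
            net = build_network(trim_to_window(annotated, window))
            summ = diversity_summary(net)
            per_window[window.mode][sample] = (len(net.vertices), summ)
            rows.append((window.mode, sample, len(net.vertices), summ))

    table = pd.DataFrame(
        [
            {
                "window": mode,
                "sample": sample,
                "n_unique": n,
                "vertex_gini": s.vertex_gini,
                "cluster_gini": s.cluster_gini,
                "max_cluster_pct": s.max_cluster_pct,
            }
            for mode, sample, n, s in rows
        ]
    )
    samples = sorted(annotated_by_sample)
    full_unique = np.array([per_window["full"][s][0] for s in samples], dtype=float)
    full_cgini = np.array([per_window["full"][s][1].cluster_gini for s in samples])
    n_unique_p = {}
    cgini_p = {}
    for window in windows:
        tu = np.array([per_window[window.mode][s][0] for s in samples], dtype=float)
        tc = np.array([per_window[window.mode][s][1].cluster_gini for s in samples])
        n_unique_p[window.mode] = _paired_p(full_unique, tu)
        cgini_p[window.mode] = _paired_p(full_cgini, tc)
    return TrimmingExperiment(table, n_unique_p, cgini_p)


# ---------------------------------------------------------------------------
# RNA vs DNA overlap
# ---------------------------------------------------------------------------

def sequence_overlap(
    rep_a: list[AnnotatedSequence], rep_b: list[AnnotatedSequence]
) -> tuple[float, pd.DataFrame, ComparisonResult | None]:
    """Fraction of A's reads whose exact sequence occurs at least once in B
    (as a percentage), the table of shared-sequence frequencies, and the
    regression of B on A frequencies over shared sequences (None when fewer
    than 2 sequences are shared)."""
    counts_a: dict[str, int] = {}
    for ann in rep_a:
        counts_a[ann.sequence] = counts_a.get(ann.sequence, 0) + ann.read_count
    counts_b: dict[str, int] = {}
    for ann in rep_b:
        counts_b[ann.sequence] = counts_b.get(ann.sequence, 0) + ann.read_count
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    if total_a == 0:
        raise ValueError("repertoire A is empty")
    shared = sorted(set(counts_a) & set(counts_b))
    pct = 100.0 * sum(counts_a[s] for s in shared) / total_a
    pairs = pd.DataFrame(
        {
            "sequence": shared,
            "freq_a": [counts_a[s] / total_a for s in shared],
            "freq_b": [counts_b[s] / total_b for s in shared],
        }
    )
    result = None
    if len(shared) >= 2:
        result = _regression(pairs["freq_a"].to_numpy(), pairs["freq_b"].to_numpy())
    return pct, pairs, result
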