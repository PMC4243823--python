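"""End-to-end orchestration: simulate -> process -> network -> usage ->
compare -> depth, plus the single-seed replica of the full experiment tree
(repeat comparisons, trimming, RNA/DNA overlap, depth curve)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .comparison import (
    TrimWindow,
    compare_usage,
    paired_gene_tests,
    sequence_overlap,
    trimming_experiment,
)
from .depth import depth_curve
from .network import build_network, diversity_summary
from .processing import FilterConfig, process_reads
from .synthetic import (
    ErrorModel,
    GermlineReference,
    amplification_jitter,
    make_germline_reference,
    sample_reads,
    simulate_repertoire,
)
from .usage import gene_usage_table, usage_from_repertoire

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reads_path: str
    reference_path: str
    out_dir: str
    platform: str = "miseq"
    forward_primers: list[str] | None = None
    reverse_primer: str | None = None
    min_median_phred: int = 32
    ig_evalue: float = 1e-10
    gene_call_evalue: float = 1e-20


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, files: list[Path]) -> dict[str, str]:
    manifest = {f.name: _sha256(f) for f in sorted(files)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Process a FASTQ through the full preparation pipeline and write the
    annotated TSV, network summary, usage table, filter report and a
    checksummed manifest. Returns the manifest."""
    out_dir = io.ensure_dir(config.out_dir)
    reference = io.read_reference_fasta(config.reference_path)
    reads = io.read_fastq(config.reads_path)
    filt = FilterConfig.for_platform(
        config.platform,
        min_median_phred=config.min_median_phred,
        ig_evalue=config.ig_evalue,
        gene_call_evalue=config.gene_call_evalue,
    )
    annotated, report = process_reads(
        reads,
        reference,
        filt,
        forward_primers=config.forward_primers,
        reverse_primer=config.reverse_primer,
        capture_trim=config.platform == "capture",
    )
    files = []
    annotated_path = out_dir / "annotated.tsv"
    io.write_annotated_tsv(annotated, annotated_path)
    files.append(annotated_path)

    report_path = out_dir / "filter_report.tsv"
    pd.DataFrame(report.stages, columns=["stage", "n_in", "n_out"]).to_csv(
        report_path, sep="\t", index=False
    )
    files.append(report_path)

    net = build_network(annotated)
    summ = diversity_summary(net)
    summary_path = out_dir / "network_summary.tsv"
    pd.DataFrame([dataclasses.asdict(summ)]).to_csv(summary_path, sep="\t", index=False)
    files.append(summary_path)

    usage_path = out_dir / "gene_usage.tsv"
    table = gene_usage_table(annotated, reference)
    pd.DataFrame(
        sorted(table.frequencies.items()), columns=["gene", "frequency"]
    ).to_csv(usage_path, sep="\t", index=False)
    files.append(usage_path)

    return _write_manifest(out_dir, files)


# ---------------------------------------------------------------------------
# full synthetic replica of the experiment tree
# ---------------------------------------------------------------------------

@dataclass
class ReplicaScale:
    """Problem sizes for the end-to-end replica; the defaults complete in
    well under a minute and preserve every qualitative contrast."""

    n_v: int = 20
    n_j: int = 3
    v_length: int = 200
    j_length: int = 50
    healthy_clones: int = 4000  # ~1 clone/read: diverse PB, most vertices seen once
    cll_clones: int = 60
    read_depth: int = 4000
    usage_depth: int = 100_000
    n_paired_samples: int = 8


def end_to_end_replica(seed: int, scale: ReplicaScale | None = None) -> pd.DataFrame:
    """Generate one healthy and one CLL synthetic sample and reproduce the
    full comparison battery: sequencing-repeat / re-amplification /
    cross-error-profile gene-usage regressions (full and low-frequency
    subsets), paired per-gene tests, the amplicon-trimming experiment, the
    RNA/DNA overlap, and network diversity per sample type. Returns a tidy
    report table (block, metric, value)."""
    scale = scale or ReplicaScale()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=128)
    reference = make_germline_reference(
        scale.n_v, scale.n_j, scale.v_length, scale.j_length, seed=int(seeds[0])
    )
    healthy = simulate_repertoire(
        reference, "healthy", scale.healthy_clones, seed=int(seeds[1])
    )
    cll = simulate_repertoire(reference, "CLL", scale.cll_clones, seed=int(seeds[2]))

    rows: list[tuple[str, str, float]] = []

    # -- resampling ladder on gene usage ------------------------------------
    # regressions pooled over several samples per arm, as in pooled-panel
    # comparisons: sequencing repeat (two read samples of the same amplified
    # pool), re-amplification repeat (finite-template resample each side),
    # cross-platform (re-amplification plus per-gene platform bias)
    ladder_samples = [healthy] + [
        simulate_repertoire(reference, "healthy", scale.healthy_clones, seed=int(seeds[100 + i]))
        for i in range(4)
    ]
    seq_a, seq_b, amp_a, amp_b, cross_a, cross_b = [], [], [], [], [], []
    for i, rep in enumerate(ladder_samples):
        base = 10 + 8 * i
        seq_a.append(usage_from_repertoire(rep, scale.usage_depth, int(seeds[base]), f"seq{i}a"))
        seq_b.append(usage_from_repertoire(rep, scale.usage_depth, int(seeds[base] + 1), f"seq{i}b"))
        a1 = amplification_jitter(rep, seed=int(seeds[base + 1]))
        a2 = amplification_jitter(rep, seed=int(seeds[base + 2]))
        amp_a.append(usage_from_repertoire(a1, scale.usage_depth, int(seeds[base + 2] + 1), f"pcr{i}a"))
        amp_b.append(usage_from_repertoire(a2, scale.usage_depth, int(seeds[base + 2] + 2), f"pcr{i}b"))
        c1 = amplification_jitter(rep, seed=int(seeds[base + 3]), gene_bias_cv=0.04)
        c2 = amplification_jitter(rep, seed=int(seeds[base + 4]), gene_bias_cv=0.04)
        cross_a.append(usage_from_repertoire(c1, scale.usage_depth, int(seeds[base + 4] + 1), f"xp{i}a"))
        cross_b.append(usage_from_repertoire(c2, scale.usage_depth, int(seeds[base + 4] + 2), f"xp{i}b"))
    seq_rep = compare_usage(seq_a, seq_b)
    seq_rep_low = compare_usage(seq_a, seq_b, subset_threshold=0.15)
    pcr_rep = compare_usage(amp_a, amp_b)
    pcr_rep_low = compare_usage(amp_a, amp_b, subset_threshold=0.15)
    cross = compare_usage(cross_a, cross_b)
    cross_low = compare_usage(cross_a, cross_b, subset_threshold=0.15)
    for block, res in [
        ("sequencing_repeat", seq_rep),
        ("sequencing_repeat_low_freq", seq_rep_low),
        ("pcr_repeat", pcr_rep),
        ("pcr_repeat_low_freq", pcr_rep_low),
        ("cross_platform", cross),
        ("cross_platform_low_freq", cross_low),
    ]:
        rows.append((block, "r_squared", res.r_squared))
        rows.append((block, "slope", res.slope))

    # -- paired per-gene tests across matched samples ------------------------
    tables1, tables2 = [], []
    for i in range(scale.n_paired_samples):
        rep = simulate_repertoire(
            reference, "healthy", scale.healthy_clones // 2, seed=int(seeds[55 + i])
        )
        tables1.append(usage_from_repertoire(rep, scale.usage_depth, int(seeds[65 + i]), f"m1_{i}"))
        tables2.append(usage_from_repertoire(rep, scale.usage_depth, int(seeds[75 + i]), f"m2_{i}"))
    paired = paired_gene_tests(tables1, tables2)
    rows.append(("paired_gene_tests", "n_significant_genes", float(len(paired.significant_genes))))
    rows.append(("paired_gene_tests", "n_genes_tested", float(len(paired.genes))))

    # -- per-sample-type networks --------------------------------------------
    summaries = {}
    for offset, (label, rep) in enumerate([("healthy", healthy), ("CLL", cll)]):
        reads = sample_reads(
            rep,
            scale.read_depth,
            material="RNA",
            error_model=ErrorModel.miseq_like(),
            seed=int(seeds[85 + offset]),
            sample_label=label,
        )
        annotated, _ = process_reads(reads, reference, FilterConfig(min_length=120))
        summ = diversity_summary(build_network(annotated))
        summaries[label] = (annotated, summ)
        rows.append((f"diversity_{label}", "vertex_gini", summ.vertex_gini))
        rows.append((f"diversity_{label}", "cluster_gini", summ.cluster_gini))
        rows.append((f"diversity_{label}", "max_cluster_pct", summ.max_cluster_pct))

    # -- trimming experiment --------------------------------------------------
    windows = [
        TrimWindow("race_250_from_J_end", race_length=150),
        TrimWindow("cdr3_only"),
        TrimWindow("capture_window", bases_from_v3prime=100, bases_from_j5prime=30),
    ]
    annotated_by_sample = {
        "healthy": summaries["healthy"][0],
        "CLL": summaries["CLL"][0],
    }
    trim = trimming_experiment(annotated_by_sample, windows)
    for _, row in trim.table.iterrows():
        rows.append(
            (f"trimming_{row['window']}_{row['sample']}", "n_unique", float(row["n_unique"]))
        )

    # -- RNA vs DNA overlap ----------------------------------------------------
    rna_reads = sample_reads(
        cll, scale.read_depth, material="RNA", error_model=ErrorModel.none(), seed=int(seeds[90])
    )
    dna_reads = sample_reads(
        cll, scale.read_depth, material="DNA", error_model=ErrorModel.none(), seed=int(seeds[91])
    )
    rna_ann, _ = process_reads(rna_reads, reference, FilterConfig(min_length=120))
    dna_ann, _ = process_reads(dna_reads, reference, FilterConfig(min_length=120))
    pct, _, overlap_reg = sequence_overlap(dna_ann, rna_ann)
    rows.append(("rna_vs_dna", "pct_dna_in_rna", pct))
    if overlap_reg is not None:
        rows.append(("rna_vs_dna", "shared_freq_r_squared", overlap_reg.r_squared))

    # -- depth model ------------------------------------------------------------
    curve = depth_curve()
    rows.append(("depth_model", "p_0.0004_at_100k", float(curve.loc[100_000, 0.0004])))
    rows.append(("depth_model", "p_0.0004_at_1M", float(curve.loc[1_000_000, 0.0004])))
    rows.append(("depth_model", "p_0.04_at_10k", float(curve.loc[10_000, 0.04])))

    return pd.DataFrame(rows, columns=["block", "metric", "value"])


def run_demo(seed: int, out_dir) -> dict[str, str]:
    """Small deterministic end-to-end demonstration; writes the replica
    report, the depth curve and a checksummed manifest."""
    out = io.ensure_dir(out_dir)
    report = end_to_end_replica(
        seed, ReplicaScale(healthy_clones=2000, read_depth=2000, usage_depth=50_000)
    )
    files = []
    report_path = out / "report.tsv"
    report.to_csv(report_path, sep="\t", index=False, float_format="%.6g")
    files.append(report_path)
    curve_path = out / "depth_curve.tsv"
    depth_curve().to_csv(curve_path, sep="\t", float_format="%.6g")
    files.append(curve_path)
    return _write_manifest(out, files)
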