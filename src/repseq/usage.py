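"""Per-sample IgHV gene-usage frequency tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .processing import AnnotatedSequence
from .synthetic import GermlineReference, TrueRepertoire


@dataclass
class GeneUsageTable:
    """Frequencies of reads assigned to each germline V gene (sums to 1 when
    any reads are present; genes with no reads appear with frequency 0)."""

    sample_id: str
    frequencies: dict[str, float]
    n_reads: int

    def __post_init__(self) -> None:
        if self.n_reads > 0:
            total = sum(self.frequencies.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, expected 1")

    def vector(self, genes: list[str]) -> np.ndarray:
        return np.array([self.frequencies.get(g, 0.0) for g in genes])


def gene_usage_table(
    annotated: list[AnnotatedSequence],
    reference: GermlineReference,
    weight_by_count: bool = True,
    sample_id: str = "sample",
) -> GeneUsageTable:
    """Compute the V gene usage table. ``weight_by_count`` weights each
    unique sequence by its read count (per-read frequencies, the default);
    otherwise every unique sequence counts once (per-vertex frequencies)."""
    genes = reference.v_names
    weights = {g: 0.0 for g in genes}
    total = 0.0
    for ann in annotated:
        if ann.v_gene not in weights:
            raise ValueError(f"{ann.read_id}: gene {ann.v_gene} not in reference")
        w = ann.read_count if weight_by_count else 1
        weights[ann.v_gene] += w
        total += w
    n_reads = int(sum(a.read_count for a in annotated))
    if total == 0:
        return GeneUsageTable(sample_id, {g: 0.0 for g in genes}, 0)
    return GeneUsageTable(sample_id, {g: w / total for g, w in weights.items()}, n_reads)


def usage_from_repertoire(
    repertoire: TrueRepertoire, depth: int, seed: int, sample_id: str = "sample"
) -> GeneUsageTable:
    """Multinomially resample ``depth`` reads over the repertoire's clones
    (error-free) and aggregate to V gene frequencies — the fast route for
    resampling experiments that do not need per-read error simulation."""
    rng = np.random.default_rng(seed)
    freqs = np.array([c.frequency for c in repertoire.clones])
    counts = rng.multinomial(depth, freqs / freqs.sum())
    genes: dict[str, float] = {}
    for clone, count in zip(repertoire.clones, counts):
        genes[clone.v_gene] = genes.get(clone.v_gene, 0.0) + count
    return GeneUsageTable(
        sample_id, {g: c / depth for g, c in genes.items()}, depth
    )


def subset_low_frequency(
    table_a: GeneUsageTable, table_b: GeneUsageTable, threshold: float
) -> list[str]:
    """Genes whose frequency is strictly below ``threshold`` in BOTH samples
    (symmetric subsetting). Used at 0.15 for the low-frequency gene-usage
    panels and at 0.02 for the RNA/DNA comparison."""
    genes = sorted(set(table_a.frequencies) | set(table_b.frequencies))
    return [
        g
        for g in genes
        if table_a.frequencies.get(g, 0.0) < threshold
        and table_b.frequencies.get(g, 0.0) < threshold
    ]
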