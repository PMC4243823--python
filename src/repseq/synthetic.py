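"""Synthetic BCR repertoire generation.

Generates toy germline V/J references, ground-truth repertoires with
somatic-hypermutation (SHM) lineages, and error-bearing sequencing reads
emulating diverse (healthy peripheral blood), lymphoblastoid cell line (LCL)
and chronic lymphocytic leukaemia (CLL) samples, for RNA or genomic-DNA
input material.

The generator is the stand-in for patient samples: clone-frequency profiles
are calibrated so that downstream network diversity measures (vertex Gini,
cluster Gini, maximum cluster size) reproduce the qualitative contrast
between diverse and clonal B-cell populations.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

#: Combined per-base substitution error rates (RT-PCR + sequencing),
#: as estimated for Illumina MiSeq and Roche 454 amplicon runs.
MISEQ_SUBSTITUTION_RATE = 2.06e-4
FOURFIVEFOUR_SUBSTITUTION_RATE = 7.04e-5  # excluding homopolymeric indels
#: Per-homopolymer-run (length >= 3) indel probability for the 454-like
#: profile. Chosen so the homopolymer contribution is of the same order as
#: the difference between the 454 combined rate (1.74e-4/base) and its
#: substitution-only rate (7.04e-5/base) on typical amplicon sequence.
FOURFIVEFOUR_HOMOPOLYMER_RATE = 2e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GermlineSegment:
    """A germline V or J gene segment with its conserved junction anchor.

    The anchor is a 0-based offset within the segment: for V segments the
    end-of-FR3 anchor (start of CDR3), for J segments the start-of-FR4
    anchor (end of CDR3).
    """

    gene_name: str
    sequence: str
    segment_class: str  # "V" or "J"
    anchor: int

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(BASES):
            raise ValueError(f"{self.gene_name}: sequence must be non-empty uppercase ACGT")
        if self.segment_class not in ("V", "J"):
            raise ValueError(f"segment_class must be V or J, got {self.segment_class!r}")
        if not 0 <= self.anchor < len(self.sequence):
            raise ValueError(f"{self.gene_name}: anchor {self.anchor} outside sequence")


@dataclass(frozen=True)
class GermlineReference:
    v_segments: tuple[GermlineSegment, ...]
    j_segments: tuple[GermlineSegment, ...]

    def __post_init__(self) -> None:
        if len(self.v_segments) < 2 or len(self.j_segments) < 1:
            raise ValueError("reference needs >=2 V segments and >=1 J segment")
        names = [s.gene_name for s in self.v_segments + self.j_segments]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        vs = self.v_segments
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                if len(vs[i].sequence) == len(vs[j].sequence):
                    if hamming(vs[i].sequence, vs[j].sequence) < 10:
                        raise ValueError(
                            f"V segments {vs[i].gene_name}/{vs[j].gene_name} differ "
                            "at <10 positions; gene assignment would be ambiguous"
                        )

    @property
    def v_names(self) -> list[str]:
        return [s.gene_name for s in self.v_segments]

    @property
    def j_names(self) -> list[str]:
        return [s.gene_name for s in self.j_segments]

    def segment(self, name: str) -> GermlineSegment:
        for s in self.v_segments + self.j_segments:
            if s.gene_name == name:
                return s
        raise KeyError(name)


@dataclass
class Clone:
    """A B-cell clone: a VDJ rearrangement plus its SHM lineage.

    ``shm_lineage`` lists (variant_sequence, within-clone fraction) pairs;
    the unmutated naive sequence is included as the first entry. SHM is
    modelled as point substitutions only, so all variants share the naive
    sequence length.
    """

    clone_id: int
    v_gene: str
    j_gene: str
    junction_insert: str
    naive_sequence: str
    frequency: float
    shm_lineage: list[tuple[str, float]]
    nonproductive_sequence: str | None = None  # second-allele rearrangement (DNA only)

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.shm_lineage)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone {self.clone_id}: lineage fractions sum to {total}")
        for seq, _ in self.shm_lineage:
            if len(seq) != len(self.naive_sequence):
                raise ValueError(f"clone {self.clone_id}: lineage variant length mismatch")


@dataclass
class TrueRepertoire:
    clones: list[Clone]
    n_cells: int
    sample_type: str  # healthy | LCL | CLL
    transcripts_per_cell: tuple[float, float] = (10.0, 2.0)  # (mean, dispersion)

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        total = sum(c.frequency for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone frequencies sum to {total}, expected 1")


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float
    homopolymer_indel_rate: float
    profile_name: str

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0 <= r <= 0.01:
                raise ValueError("error rates must lie in [0, 0.01]")
        if self.profile_name == "miseq_like" and self.homopolymer_indel_rate != 0:
            raise ValueError("miseq_like profile has no homopolymer indels")

    @classmethod
    def miseq_like(cls, substitution_rate: float = MISEQ_SUBSTITUTION_RATE) -> "ErrorModel":
        return cls(substitution_rate, 0.0, "miseq_like")

    @classmethod
    def fourfivefour_like(
        cls,
        substitution_rate: float = FOURFIVEFOUR_SUBSTITUTION_RATE,
        homopolymer_indel_rate: float = FOURFIVEFOUR_HOMOPOLYMER_RATE,
    ) -> "ErrorModel":
        return cls(substitution_rate, homopolymer_indel_rate, "fourfiveFour_like")

    @classmethod
    def none(cls) -> "ErrorModel":
        return cls(0.0, 0.0, "none")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


@dataclass
class ReadSet:
    reads: list[Read]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids must be unique")

    def __len__(self) -> int:
        return len(self.reads)

    def subset(self, keep_ids: set[str]) -> "ReadSet":
        return ReadSet([r for r in self.reads if r.read_id in keep_ids], dict(self.metadata))


# ---------------------------------------------------------------------------
# germline reference
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_germline_reference(
    n_v: int,
    n_j: int,
    v_length: int = 200,
    j_length: int = 50,
    seed: int = 0,
) -> GermlineReference:
    """Generate a toy germline V/J segment library.

    Segments are independent random sequences (pairwise V Hamming distance
    is verified to be >=10, so toy gene assignment is unambiguous). V
    anchors sit 10 bases from the segment 3' end (end of FR3); J anchors
    10 bases in from the 5' end (start of FR4).
    """
    if n_v < 2 or n_j < 1:
        raise ValueError("need n_v >= 2 and n_j >= 1")
    if v_length < 150 or j_length < 40:
        raise ValueError("need v_length >= 150 and j_length >= 40")
    rng = np.random.default_rng(seed)
    v_segments: list[GermlineSegment] = []
    while len(v_segments) < n_v:
        seq = _random_seq(rng, v_length)
        if all(hamming(seq, s.sequence) >= 10 for s in v_segments):
            v_segments.append(
                GermlineSegment(f"IGHV{len(v_segments) + 1}-toy", seq, "V", v_length - 10)
            )
    j_segments = [
        GermlineSegment(f"IGHJ{i + 1}-toy", _random_seq(rng, j_length), "J", 10)
        for i in range(n_j)
    ]
    return GermlineReference(tuple(v_segments), tuple(j_segments))


# ---------------------------------------------------------------------------
# repertoire simulation
# ---------------------------------------------------------------------------

HEALTHY_DIRICHLET_ALPHA = 10.0  # flat-ish profile of a diverse repertoire
HEALTHY_MAX_FREQUENCY = 0.05
DOMINANT_CLONE_MIN = 0.60
NONPRODUCTIVE_FRACTION = 0.3  # clones carrying a second, nonproductive allele

SAMPLE_TYPES = ("healthy", "LCL", "CLL")


def _capped_dirichlet(rng: np.random.Generator, n: int, alpha: float, cap: float) -> np.ndarray:
    """Symmetric Dirichlet draw with an upper cap enforced by water-filling."""
    freqs = rng.dirichlet(np.full(n, alpha))
    if n * cap <= 1.0:
        raise ValueError("cap too small for n clones")
    for _ in range(100):
        over = freqs > cap
        if not over.any():
            break
        excess = (freqs[over] - cap).sum()
        freqs[over] = cap
        under = ~over
        freqs[under] += excess * freqs[under] / freqs[under].sum()
    return freqs / freqs.sum()


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Apply exactly n_sub substitutions at distinct random positions."""
    n_sub = min(n_sub, len(seq))
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def _lineage(
    rng: np.random.Generator,
    naive: str,
    shm_rate: float,
    n_variants: int,
    naive_fraction: float,
) -> list[tuple[str, float]]:
    if n_variants == 0:
        return [(naive, 1.0)]
    fracs = rng.dirichlet(np.ones(n_variants)) * (1.0 - naive_fraction)
    lineage = [(naive, naive_fraction)]
    for frac in fracs:
        n_sub = 1 + rng.poisson(shm_rate * len(naive))
        lineage.append((_mutate(rng, naive, n_sub), float(frac)))
    total = sum(f for _, f in lineage)
    return [(s, f / total) for s, f in lineage]


def simulate_repertoire(
    reference: GermlineReference,
    sample_type: str,
    n_clones: int,
    shm_rate: float = 0.002,
    seed: int = 0,
    n_cells: int = 100_000,
    nonproductive_fraction: float = NONPRODUCTIVE_FRACTION,
) -> TrueRepertoire:
    """Simulate a ground-truth repertoire for one sample.

    healthy: clone frequencies from a flat symmetric Dirichlet capped at 5%
    (no clone dominates a diverse repertoire). CLL/LCL: one dominant clone
    at >=60% (Beta(8,2)-drawn, rejected below 0.6) over a Dirichlet
    background. V genes are used unevenly (Zipf weights over the reference),
    so some genes exceed 15% usage while most sit below — the regime the
    low-frequency subsetting analyses rely on.

    SHM lineages are substitution-only; a configurable fraction of clones
    carries a nonproductive second-allele rearrangement observable only in
    genomic DNA.
    """
    if sample_type not in SAMPLE_TYPES:
        raise ValueError(f"unknown sample_type {sample_type!r}; expected one of {SAMPLE_TYPES}")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not 0 <= shm_rate <= 0.05:
        raise ValueError("shm_rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)

    if sample_type == "healthy" or n_clones == 1:
        if n_clones == 1:
            freqs = np.array([1.0])
        else:
            cap = max(HEALTHY_MAX_FREQUENCY, 1.5 / n_clones)
            freqs = _capped_dirichlet(rng, n_clones, HEALTHY_DIRICHLET_ALPHA, cap)
    else:
        while True:
            dominant = float(rng.beta(8, 2))
            if dominant >= DOMINANT_CLONE_MIN:
                break
        if n_clones == 1:
            freqs = np.array([1.0])
        else:
            background = rng.dirichlet(np.ones(n_clones - 1)) * (1.0 - dominant)
            freqs = np.concatenate([[dominant], background])
    freqs = freqs / freqs.sum()

    v_weights = _zipf_weights(len(reference.v_segments))
    clones: list[Clone] = []
    for cid, freq in enumerate(freqs):
        v = reference.v_segments[rng.choice(len(reference.v_segments), p=v_weights)]
        j = reference.j_segments[rng.integers(0, len(reference.j_segments))]
        insert = _random_seq(rng, int(rng.integers(6, 19)))
        naive = v.sequence + insert + j.sequence

        dominant_clone = sample_type != "healthy" and cid == 0
        if shm_rate == 0:
            n_var = 0
            naive_frac = 1.0
        elif dominant_clone:
            # CLL/LCL dominant clones are lineages with one overwhelming member
            n_var = int(rng.integers(2, 5))
            naive_frac = float(rng.uniform(0.88, 0.96))
        elif rng.random() < 0.4:
            n_var = int(rng.integers(1, 4))
            naive_frac = float(rng.uniform(0.5, 0.9))
        else:
            n_var = 0
            naive_frac = 1.0
        lineage = _lineage(rng, naive, shm_rate, n_var, naive_frac)

        nonproductive = None
        if rng.random() < nonproductive_fraction:
            v2 = reference.v_segments[rng.choice(len(reference.v_segments), p=v_weights)]
            j2 = reference.j_segments[rng.integers(0, len(reference.j_segments))]
            # out-of-frame junction: any random insert; sequence just has to differ
            nonproductive = v2.sequence + _random_seq(rng, int(rng.integers(5, 17))) + j2.sequence

        clones.append(
            Clone(
                clone_id=cid,
                v_gene=v.gene_name,
                j_gene=j.gene_name,
                junction_insert=insert,
                naive_sequence=naive,
                frequency=float(freq),
                shm_lineage=lineage,
                nonproductive_sequence=nonproductive,
            )
        )
    return TrueRepertoire(clones=clones, n_cells=n_cells, sample_type=sample_type)


def _with_frequencies(repertoire: TrueRepertoire, freqs: np.ndarray) -> TrueRepertoire:
    clones = [dataclasses.replace(c, frequency=float(f)) for c, f in zip(repertoire.clones, freqs)]
    return TrueRepertoire(
        clones=clones,
        n_cells=repertoire.n_cells,
        sample_type=repertoire.sample_type,
        transcripts_per_cell=repertoire.transcripts_per_cell,
    )


def amplification_jitter(
    repertoire: TrueRepertoire,
    seed: int,
    n_templates: int = 20_000,
    gene_bias_cv: float = 0.0,
) -> TrueRepertoire:
    """Emulate an independent amplification of the same RNA/cDNA pool.

    A fresh aliquot contains a finite number of template molecules, so the
    clone frequencies entering PCR are a multinomial resample of the true
    frequencies over ``n_templates`` molecules — the source of the extra
    re-sampling stochasticity seen between RT-PCR repeats relative to
    re-sequencing the same product. ``gene_bias_cv`` > 0 additionally
    multiplies each V gene's clones by a lognormal efficiency factor,
    emulating method/platform-specific capture or primer bias.
    """
    if n_templates <= 0:
        raise ValueError("n_templates must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.array([c.frequency for c in repertoire.clones])
    counts = rng.multinomial(n_templates, freqs / freqs.sum())
    new = counts.astype(float)
    if gene_bias_cv > 0:
        genes = sorted({c.v_gene for c in repertoire.clones})
        sigma = np.sqrt(np.log1p(gene_bias_cv**2))
        factors = {g: rng.lognormal(-sigma**2 / 2, sigma) for g in genes}
        new *= np.array([factors[c.v_gene] for c in repertoire.clones])
    total = new.sum()
    if total == 0:
        raise ValueError("no template molecules drawn; increase n_templates")
    return _with_frequencies(repertoire, new / total)


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """0-based half-open [start, end) spans of homopolymer runs of length >= min_len."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _sampling_entries(
    repertoire: TrueRepertoire, material: str, rng: np.random.Generator
) -> list[tuple[float, str, int, str, str]]:
    """(weight, sequence, clone_id, v_gene, j_gene) templates for sampling.

    RNA weights each clone by frequency x a clone-level transcript-burden
    factor (gamma with the repertoire's dispersion, mean 1); DNA weights by
    cell frequency and adds the nonproductive second allele at equal weight.
    """
    entries = []
    _, dispersion = repertoire.transcripts_per_cell
    for clone in repertoire.clones:
        if material == "RNA":
            burden = rng.gamma(dispersion, 1.0 / dispersion)
            base = clone.frequency * burden
        else:
            base = clone.frequency
        for seq, frac in clone.shm_lineage:
            entries.append((base * frac, seq, clone.clone_id, clone.v_gene, clone.j_gene))
        if material == "DNA" and clone.nonproductive_sequence is not None:
            entries.append(
                (clone.frequency, clone.nonproductive_sequence, clone.clone_id, "", "")
            )
    return entries


def _apply_errors(seq: str, error_model: ErrorModel, rng: np.random.Generator) -> str:
    out = seq
    if error_model.substitution_rate > 0:
        n_err = rng.binomial(len(out), error_model.substitution_rate)
        if n_err:
            out = _mutate(rng, out, n_err)
    if error_model.homopolymer_indel_rate > 0 and error_model.profile_name == "fourfiveFour_like":
        runs = _homopolymer_runs(out)
        if runs:
            hits = rng.random(len(runs)) < error_model.homopolymer_indel_rate
            if hits.any():
                chars = list(out)
                # apply right-to-left so earlier spans stay valid
                for (start, end), hit in sorted(zip(runs, hits), reverse=True):
                    if not hit:
                        continue
                    if rng.random() < 0.5:
                        chars.insert(start, chars[start])  # +1 run length
                    else:
                        del chars[start]  # -1 run length
                out = "".join(chars)
    return out


def sample_reads(
    repertoire: TrueRepertoire,
    depth: int,
    material: str = "RNA",
    error_model: ErrorModel | None = None,
    read_window: tuple[int, int] | None = None,
    seed: int = 0,
    low_quality_fraction: float = 0.0,
    phred: int = 38,
    low_phred: int = 20,
    sample_label: str = "sample",
    platform: str = "miseq",
) -> ReadSet:
    """Sample ``depth`` reads from the repertoire with sequencing errors.

    Substitution errors are applied i.i.d. per base; homopolymer indels per
    run of length >=3 for the 454-like profile. ``read_window`` crops reads
    to a (start, end) slice of the template to emulate platform read
    lengths. Quality strings are constant Phred (default 38) except for a
    configurable low-quality fraction at Phred 20, which exercises the
    median quality filter downstream.

    The returned metadata carries the ground truth: read_id -> (clone_id,
    v_gene, j_gene); nonproductive-allele reads have empty gene fields.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if material not in ("RNA", "DNA"):
        raise ValueError("material must be RNA or DNA")
    error_model = error_model or ErrorModel.none()
    rng = np.random.default_rng(seed)

    entries = _sampling_entries(repertoire, material, rng)
    weights = np.array([e[0] for e in entries])
    weights = weights / weights.sum()
    counts = rng.multinomial(depth, weights)

    if read_window is not None:
        start, end = read_window
        max_len = max(len(e[1]) for e in entries)
        if start < 0 or end <= start or start >= max_len:
            raise ValueError(f"read window {read_window} outside sequence bounds")

    reads: list[Read] = []
    truth: dict[str, tuple[int, str, str]] = {}
    idx = 0
    for (weight, template, clone_id, v_gene, j_gene), count in zip(entries, counts):
        for _ in range(count):
            seq = _apply_errors(template, error_model, rng)
            if read_window is not None:
                seq = seq[read_window[0]: read_window[1]]
            q = phred
            if low_quality_fraction > 0 and rng.random() < low_quality_fraction:
                q = low_phred
            rid = f"read_{idx:07d}"
            reads.append(Read(rid, seq, chr(q + 33) * len(seq)))
            truth[rid] = (clone_id, v_gene, j_gene)
            idx += 1
    # deterministic shuffle so read order does not encode clone identity
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return ReadSet(
        reads=reads,
        metadata={
            "sample": sample_label,
            "material": material,
            "platform": platform,
            "truth": truth,
        },
    )
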