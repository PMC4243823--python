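"""FASTA/FASTQ/TSV plumbing (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .processing import AnnotatedSequence
from .synthetic import GermlineReference, GermlineSegment, Read, ReadSet, TrueRepertoire


def write_reference_fasta(reference: GermlineReference, path) -> None:
    records = [
        SeqRecord(
            Seq(seg.sequence),
            id=seg.gene_name,
            description=f"class={seg.segment_class} anchor={seg.anchor}",
        )
        for seg in reference.v_segments + reference.j_segments
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path) -> GermlineReference:
    """Read a germline reference written by :func:`write_reference_fasta`
    (segment class and anchor carried in the description)."""
    v, j = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=") for kv in rec.description.split()[1:])
        seg = GermlineSegment(
            gene_name=rec.id,
            sequence=str(rec.seq).upper(),
            segment_class=fields["class"],
            anchor=int(fields["anchor"]),
        )
        (v if seg.segment_class == "V" else j).append(seg)
    return GermlineReference(tuple(v), tuple(j))


def write_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for read in reads.reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")


def read_fastq(path, metadata: dict | None = None) -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quality = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq).upper(), quality))
    return ReadSet(reads, metadata or {})


def write_truth_tsv(repertoire: TrueRepertoire, path) -> None:
    rows = [
        {
            "clone_id": c.clone_id,
            "v_gene": c.v_gene,
            "j_gene": c.j_gene,
            "frequency": c.frequency,
            "sequence": c.naive_sequence,
        }
        for c in repertoire.clones
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_annotated_tsv(annotated: list[AnnotatedSequence], path) -> None:
    rows = [
        {
            "read_id": a.read_id,
            "sequence": a.sequence,
            "v_gene": a.v_gene,
            "j_gene": a.j_gene,
            "v_start": a.v_span[0],
            "v_end": a.v_span[1],
            "j_start": a.j_span[0],
            "j_end": a.j_span[1],
            "junction_start": a.junction_span[0],
            "junction_end": a.junction_span[1],
            "read_count": a.read_count,
        }
        for a in annotated
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotated_tsv(path) -> list[AnnotatedSequence]:
    df = pd.read_csv(path, sep="\t")
    return [
        AnnotatedSequence(
            read_id=str(r.read_id),
            sequence=str(r.sequence),
            v_gene=str(r.v_gene),
            j_gene=str(r.j_gene),
            v_span=(int(r.v_start), int(r.v_end)),
            j_span=(int(r.j_start), int(r.j_end)),
            junction_span=(int(r.junction_start), int(r.junction_end)),
            read_count=int(r.read_count),
        )
        for r in df.itertuples()
    ]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
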